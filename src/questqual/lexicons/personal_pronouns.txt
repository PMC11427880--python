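# First/second/third person pronouns referring to people.
i
me
my
mine
myself
we
us
our
ours
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
they
them
their
theirs
themselves
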