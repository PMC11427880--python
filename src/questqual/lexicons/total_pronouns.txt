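# Union of personal and impersonal pronouns.
another
anybody
anyone
anything
everybody
everyone
everything
he
her
hers
herself
him
himself
his
i
it
its
itself
me
mine
my
myself
nobody
nothing
other
others
our
ours
ourselves
she
somebody
someone
something
stuff
that
their
theirs
them
themselves
these
they
thing
things
this
those
us
we
what
which
who
whom
whose
you
your
yours
yourself
yourselves
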