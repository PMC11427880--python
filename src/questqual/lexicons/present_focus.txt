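is
am
are
be
being
now
today
currently
current
nowadays
present
presently
have
has
do
does
want
wants
need
needs
feel
feels
know
knows
think
thinks
take
takes
happen
happens
ongoing
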