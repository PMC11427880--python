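# Pronouns not referring to a person.
it
its
itself
this
that
these
those
what
which
who
whom
whose
something
anything
nothing
everything
somebody
anybody
nobody
everybody
someone
anyone
everyone
other
others
another
stuff
thing
things
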