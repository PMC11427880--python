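# Interrogative (question-forming) words. Contracted forms ("what's")
# are also matched through the tokenizer's contraction-expansion table;
# they are listed here as well so the file is self-contained.
who
whom
whose
what
which
where
when
why
how
who's
who're
who'd
who'll
what's
what're
what'd
what'll
where's
where'd
when's
when'd
why's
why'd
how's
how'd
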