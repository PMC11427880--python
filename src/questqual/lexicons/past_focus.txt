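was
were
had
did
done
been
ago
yesterday
earlier
previously
previous
formerly
former
went
got
said
told
took
gave
came
made
felt
found
saw
knew
thought
happened
started
began
stopped
diagnosed
prescribed
tried
used
ended
finished
lasted
caused
historically
history
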