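will
going
gonna
soon
tomorrow
future
shall
might
may
hope
hopes
hoping
plan
plans
planning
expect*
predict*
upcoming
later
eventually
anticipat*
prospect*
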