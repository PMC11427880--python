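amazing
awesome
best
better
calm*
comfort*
enjoy*
excite*
fine
glad
good
grateful
great
happiness
happy
hope
hopeful
hopes
hoping
improve*
love
loved
loves
loving
luckily
lucky
nice
ok
okay
positive
relief
relieved
safe
safely
thank*
wonderful
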