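angry
anger
angrily
mad
furious
rage
rages
raging
hate
hates
hated
hating
annoy*
frustrat*
irritat*
outrage*
pissed
resent*
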