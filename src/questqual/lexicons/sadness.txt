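sad
sadness
sadly
depress*
cry
crying
cried
tears
grief
griev*
hopeless*
miserable
lonely
loneliness
heartbroken
sorrow*
unhappy
devastat*
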