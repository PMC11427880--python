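# Negative emotion: superset of anxiety, anger and sadness.
afraid
anger
angrily
angry
annoy*
anxiety
anxious*
awful
bad
cried
cry
crying
depress*
devastat*
difficult*
dread*
embarrass*
fear
fearful
fears
frustrat*
furious
grief
griev*
guilt*
hate
hated
hates
hating
heartbroken
helpless
hopeless*
horrible
hurt
hurting
hurts
irritat*
loneliness
lonely
mad
miserable
nasty
negative
nervous*
outrage*
panic*
pissed
problem*
rage
rages
raging
resent*
sad
sadly
sadness
scare
scared
scares
scary
shame*
sorrow*
stress*
suffer*
tears
tense
tension
terrible
trouble*
uneasy
unhappy
upset*
worried
worries
worry
worrying
worse
worst
worthless
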