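# Overall affect: union of positive and negative emotion.
afraid
amazing
anger
angrily
angry
annoy*
anxiety
anxious*
awesome
awful
bad
best
better
calm*
comfort*
cried
cry
crying
depress*
devastat*
difficult*
dread*
embarrass*
enjoy*
excite*
fear
fearful
fears
fine
frustrat*
furious
glad
good
grateful
great
grief
griev*
guilt*
happiness
happy
hate
hated
hates
hating
heartbroken
helpless
hope
hopeful
hopeless*
hopes
hoping
horrible
hurt
hurting
hurts
improve*
irritat*
loneliness
lonely
love
loved
loves
loving
luckily
lucky
mad
miserable
nasty
negative
nervous*
nice
ok
okay
outrage*
panic*
pissed
positive
problem*
rage
rages
raging
relief
relieved
resent*
sad
sadly
sadness
safe
safely
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
thank*
trouble*
uneasy
unhappy
upset*
wonderful
worried
worries
worry
worrying
worse
worst
worthless
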