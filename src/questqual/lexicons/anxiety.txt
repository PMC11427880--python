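anxious*
anxiety
worry
worried
worries
worrying
nervous*
afraid
scared
scare
scares
scary
fear
fears
fearful
panic*
stress*
tense
tension
uneasy
dread*
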