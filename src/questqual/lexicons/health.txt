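health*
doctor*
nurse*
hospital*
clinic*
medical
medicine*
medication*
pill
pills
drug
drugs
dose
doses
dosage*
sick*
ill
illness*
disease*
symptom*
diagnos*
treat
treats
treated
treating
treatment*
therapy
therapies
surgery
surgeries
surgical*
pain
pains
painful
ache*
aching
infection*
infected
dialysis
transplant*
cancer*
diabet*
chronic
acute
test
tests
tested
testing
checkup*
prescri*
vitamin*
diet
diets
dietary
flu
fever*
nausea*
fatigue*
injur*
wound*
recover*
heal
healing
condition*
failure
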