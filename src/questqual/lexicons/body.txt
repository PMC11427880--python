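body
bodies
kidney*
heart
hearts
blood
head
arm
arms
leg
legs
stomach*
skin
bone
bones
muscle*
liver
lung
lungs
brain
eye
eyes
ear
ears
hand
hands
foot
feet
chest
bladder
urine
urinary
throat
mouth
teeth
tooth
face
neck
shoulder*
knee
knees
hip
hips
organ
organs
cell
cells
nerve*
vein*
belly
abdomen
abdominal
spine
tissue*
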