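# Curated syllable counts for common and health-domain words.
# word<TAB>count; consulted before the heuristic fallback.
abdomen	3
abdominal	4
ability	4
ache	1
acid	2
acute	2
age	1
albumin	3
allergic	3
allergy	3
anemic	3
answer	2
antibiotic	5
anxiety	4
appetite	3
arm	1
arthritis	3
autoimmune	4
back	1
bacteria	4
belly	2
biopsy	3
bladder	2
bloated	2
blood	1
body	2
bone	1
burning	2
calcium	3
cancer	2
capacity	4
care	1
cell	1
chances	2
checkup	2
chemistry	3
chemotherapy	5
chest	1
child	1
cholesterol	4
chronic	2
clinic	2
clot	1
condition	3
congenital	4
cramp	1
creatinine	4
cure	1
cyst	1
daily	2
damage	2
dangerous	3
daughter	2
day	1
deficiency	4
depression	3
detox	2
diabetes	4
diagnose	3
diagnosed	3
diagnosis	4
diagnostic	4
dialysis	4
disability	5
disease	2
dizzy	2
doctor	2
donation	3
donor	2
dose	1
doses	2
drug	1
ear	1
early	2
electrolyte	4
emergency	4
energy	3
enzyme	2
exercise	3
exhausted	3
eye	1
failure	2
family	3
faster	2
father	2
fatigue	2
fatigued	2
feet	1
female	2
fever	2
filter	2
filtration	3
flu	1
fluid	2
food	1
foot	1
frequent	2
frequently	3
function	2
genetic	3
gland	1
glucose	2
health	1
healthy	2
heart	1
help	1
hemoglobin	4
hepatitis	4
hereditary	5
hip	1
history	3
hospital	3
husband	2
hydration	3
hypertension	4
hypertensive	4
ill	1
illness	2
immune	2
immunity	4
infect	2
infection	3
inflamed	2
inflammation	4
injure	2
injury	3
insulin	3
itching	2
kidney	2
knee	1
lab	1
late	1
leg	1
level	2
liver	2
lower	2
lung	1
magnesium	4
male	1
man	1
medical	3
medication	4
medicine	3
men	1
metabolic	4
metabolism	4
mild	1
mineral	3
month	1
monthly	2
mother	2
mouth	1
muscle	2
neck	1
nephritis	3
nephrologist	4
nerve	1
night	1
numb	1
nurse	1
nutrition	3
often	2
operation	4
organ	2
pain	1
painful	2
palliative	4
pathology	4
patient	2
permanent	3
physician	3
pill	1
potassium	4
prescribe	2
prescription	3
pressure	2
preventative	4
prevention	3
preventive	3
problem	2
procedure	3
protein	2
question	2
radiation	4
radiology	5
rash	1
recovery	4
regularly	4
salt	1
scan	1
serious	3
seriously	4
severe	2
sick	1
skin	1
sleep	1
slower	2
sodium	3
specialist	3
spine	1
stable	2
stage	1
stages	2
stomach	2
stone	1
strain	1
sufficiency	4
sugar	2
surgeon	2
surgery	3
swell	1
swelling	2
swollen	2
symptom	2
symptomatic	4
tablet	2
teeth	1
temporary	4
terminal	3
test	1
therapy	3
throat	1
tissue	2
transplant	2
transplantation	4
transplanted	3
treatable	3
treated	2
treatment	2
tumor	2
ulcer	2
ultrasound	3
unstable	3
upper	2
urinary	4
urinate	3
urine	2
urologist	4
vein	1
viral	2
virus	2
vitamin	3
vomit	2
water	2
week	1
weekly	2
weight	1
woman	2
women	2
workup	2
wound	1
year	1
yearly	2
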