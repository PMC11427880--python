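# Social processes: references to other people (including
# clinicians) plus communication and interaction words.
# Superset of family, friend, female_refs and male_refs.
advice
answer*
anyone
ask*
asked
aunt
aunts
babies
baby
bestie*
boy*
brother*
buddies
buddy
call*
called
chat*
child
children
community*
companion*
conversation*
cousin*
dad
dads
daughter*
discuss*
doctor*
everyone
families
family
father*
female*
friend*
gentleman
gentlemen
girl*
grandfather*
grandma
grandmother*
grandpa
group*
guy*
he
he'd
he'll
he's
her
hers
herself
him
himself
his
husband*
kid
kids
ladies
lady
listen*
madam
male*
man
meet*
member*
men
met
miss
mom
moms
mother*
mr
mrs
ms
mum
neighbor*
neighbour*
nephew*
niece*
nurse*
our
pal
pals
parent*
people
person*
roommate*
share*
shared
she
she'd
she'll
she's
sibling*
sir
sister*
social*
somebody
son
sons
spouse*
support*
talk*
tell*
their
them
they
together
told
uncle*
us
visit*
we
wife
wives
woman
women
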