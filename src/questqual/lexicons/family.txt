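family
families
mom
moms
mum
mother*
dad
dads
father*
parent*
brother*
sister*
son
sons
daughter*
grandma
grandpa
grandmother*
grandfather*
husband*
wife
wives
aunt
aunts
uncle*
cousin*
baby
babies
kid
kids
child
children
niece*
nephew*
sibling*
spouse*
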