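he
him
his
himself
he's
he'd
he'll
man
men
male*
boy*
guy*
gentleman
gentlemen
dad
dads
father*
brother*
son
sons
husband*
uncle*
grandpa
grandfather*
mr
sir
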