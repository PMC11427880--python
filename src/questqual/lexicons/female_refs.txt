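she
her
hers
herself
she's
she'd
she'll
woman
women
female*
girl*
lady
ladies
mom
moms
mum
mother*
sister*
daughter*
wife
wives
aunt
aunts
grandma
grandmother*
miss
mrs
ms
madam
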