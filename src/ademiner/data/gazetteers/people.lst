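# Relatives and other third parties: mention refers to someone else
mother
father
brother
sister
husband
wife
son
daughter
aunt
uncle
cousin
grandmother
grandfather
mum
dad
neighbour
friend
flatmate
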