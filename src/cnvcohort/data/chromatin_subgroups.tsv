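state	subgroup
TssA	active_TSS
PromU	promoter
PromD1	promoter
PromD2	promoter
Tx5	transcribed
Tx	transcribed
Tx3	transcribed
TxWk	transcribed
TxReg	transcribed_regulatory
TxEnh5	transcribed_regulatory
TxEnh3	transcribed_regulatory
TxEnhW	transcribed_regulatory
EnhA1	active_enhancer
EnhA2	active_enhancer
EnhAF	active_enhancer
EnhW1	weak_enhancer
EnhW2	weak_enhancer
EnhAc	weak_enhancer
DNase	DNase
ZNF/Rpts	ZNF_repeats
Het	heterochromatin
PromP	poised_promoter
PromBiv	bivalent_promoter
ReprPC	repressed_polycomb
Quies	none
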