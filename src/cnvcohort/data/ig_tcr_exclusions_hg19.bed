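chr2	88937988	89411302	IG_kappa
chr7	38279624	38407656	TCR_gamma
chr7	141998850	142510972	TCR_beta
chr14	21159896	22090937	IG
chr14	22090056	23021075	TCR_alpha
chr14	22891536	22935569	TCR_delta
chr14	105065300	106352275	IG
chr14	106032613	107288051	IGH
chr16	33740715	33741266	IGH
chr22	20715571	21595082	IG_lambda
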