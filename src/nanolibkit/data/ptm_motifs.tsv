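motif_regex	liability_class	risk_tier
N[^P][ST]	n_glycosylation	high
NG	deamidation	high
NS	deamidation	high
NT	deamidation	high
DG	isomerization	high
DS	isomerization	high
DT	isomerization	high
DP	hydrolysis	high
NN	deamidation	medium
NA	deamidation	medium
M	oxidation	medium
W	oxidation	medium
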