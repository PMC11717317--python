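outcome	egger_intercept	egger_intercept_pval	q_stat	q_pval
AS	-0.007	0.358	50.67	0.099
AIS	-0.002	0.778	50.74	0.099
CES	-0.005	0.774	56.09	0.037
LAS	-0.006	0.789	52.66	0.071
SVS	-0.035	0.078	58.47	0.023
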