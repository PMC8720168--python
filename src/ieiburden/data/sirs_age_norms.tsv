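age_low	age_high	hr_p90	rr_p90
0	1	180	40
1	2	160	30
2	6	140	22
6	13	130	18
13	18.01	110	14
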