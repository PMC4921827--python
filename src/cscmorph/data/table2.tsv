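model	order	area_nm2
8tmh	2	28.7
8tmh	3	41.9
8tmh	4	47.2
8tmh	5	65.2
8tmh	6	82.1
7tmh_cesa	2	30.4
7tmh_cesa	3	44.4
7tmh_cesa	4	49.4
7tmh_cesa	5	62.1
7tmh_cesa	6	88.0
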