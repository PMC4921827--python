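group	geometry	supergroup	perimeter_nm	perimeter_sd	diameter_nm	diameter_sd	lobe_area_nm2	lobe_area_sd	n_particles	n_lobes
original	circle	original	78.4	4.9	24.9	1.6	39.9	6.5	324	300
original	hexagon	original	74.8	4.5	21.4	1.3				324
isac	circle	class_averages	76.8	2.5	24.3	0.8	37.6	3.3	6	36
isac	hexagon	class_averages	78.0	3.1	22.5	0.9				6
relion	circle	class_averages	78.2	0.4	24.9	0.1	42.0	2.7	2	12
relion	hexagon	class_averages	79.9	1.5	23.1	0.4				2
eman2	circle	class_averages	76.4	2.3	24.3	0.7	36.7	4.9	6	36
eman2	hexagon	class_averages	78.7	1.9	22.7	0.5				6
lobes_6class		class_averages					40.6	4.4		6
lobes_12class		class_averages					38.7	2.9		12
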