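name	value	unit
opposite_lobe_spacing_mean_nm	17.0	nm
opposite_lobe_spacing_sd_nm	0.7	nm
opposite_lobe_spacing_min_nm	15.1	nm
opposite_lobe_spacing_max_nm	18.6	nm
five_lobed_fraction	0.09	fraction
n_particles_total	497	count
n_particles_measured	324	count
n_lobes_picked	916	count
particle_box_nm	31.6	nm
lobe_box_nm	10.3	nm
cytosolic_diameter_sixfold_trimer_nm	32.8	nm
cytosolic_diameter_saxs_schematic_nm	27	nm
negstain_trimer_area_nm2	108.7	nm2
computational_cytosolic_trimer_area_nm2	104.1	nm2
saxs_trimer_area_nm2	99.6	nm2
blur_resolution_nm	2.5	nm
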