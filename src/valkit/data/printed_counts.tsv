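target_id	kind	x	n	expected_pct	expected_lower_pct	expected_upper_pct	extra
lob_fpr_overall	proportion	0	60	0.00
lob_fpr_sample	proportion	0	12	0.00
lod_hit_rate_20_of_20	proportion	20	20	100.00	83.89	100.00
lod_hit_rate_19_of_19	proportion	19	19	100.00	83.18	100.00
lod_hit_rate_18_of_18	proportion	18	18	100.00	82.41	100.00
lod_hit_rate_15_of_15	proportion	15	15	100.00	79.61	100.00
lod_hit_rate_14_of_14	proportion	14	14	100.00	78.47	100.00
lod_hit_rate_13_of_13	proportion	13	13	100.00	77.19	100.00
lod_overall_median	median			23.04			23.04,24.51,12.21
concordance_ppa	ppa			90.00	82.56	94.48	a=90;b=7;c=10;d=119;unknown_pos=1;unknown_neg=2
concordance_npa	npa			94.44	88.98	97.28	a=90;b=7;c=10;d=119;unknown_pos=1;unknown_neg=2
concordance_npa_with_unknowns	npa_with_unknowns			92.97			a=90;b=7;c=10;d=119;unknown_pos=1;unknown_neg=2
precision_repro_positive_overall	proportion	389	391	99.49	98.15	99.86
precision_repro_negative_overall	proportion	363	364	99.73	98.46	99.95
precision_repeatability_overall	proportion	368	371	99.19	97.65	99.72
precision_repro_35_of_36	proportion	35	36	97.22	85.83	99.51
precision_repeat_17_of_18	proportion	17	18	94.44	74.24	99.01
precision_repro_11_of_11	proportion	11	11	100.00	74.12	100.00
interference_necrotic_50pct	proportion	1	2	50.00
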