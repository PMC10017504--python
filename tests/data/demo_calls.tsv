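ref_name	pos	pos_1based	motif5	treated_rate	treated_coverage	treated_del_count	input_rate	input_coverage	fold_over_background	fraction	tier	calibration_fallback
demo_t001	95	96	GCUAC	0.164336	286	47	0.00333333	300	16.4336	0.234179	confident	1
demo_t002	22	23	GCUCU	0.318352	267	85	0	300	31.8352	0.447333	confident	1
demo_t003	48	49	GGUAA	0.6	250	150	0	300	60	0.78817	confident	1
demo_t004	47	48	UCUGG	0.790514	253	200	0	300	79.0514	0.988973	confident	1
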