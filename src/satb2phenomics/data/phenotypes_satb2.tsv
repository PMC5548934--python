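individual_id	mutation_class	neurodevelopmental_impairment	absent_or_near_absent_speech	normal_somatic_growth	cleft_palate	drooling	dental_anomalies	happy_demeanor
P01	lof	1	1	1	1	1	0	0
P02	lof	1	1	1	1	1	1	0
P03	lof	1	0	1	0	1	0	0
P04	lof	1	1	1	1	1	0	0
P05	lof	1	1	0	0	1	1	0
P06	lof	1	1	1	1	1	0	0
P07	lof	1	1	1	0	1	0	1
P08	lof	1	0	1	0	0	1	0
P09	lof	1	1	1	1	0	0	0
P10	lof	1	1	1	0	0	1	0
P11	lof	1	1	1	0	0	0	0
P12	missense	1	1	1	1	1	0	0
P13	missense	1	1	1	0	1	1	0
P14	missense	1	1	1	1	0	0	0
P15	missense	1	0	1	0	1	0	0
P16	missense	1	1	1	1	0	1	0
P17	missense	1	1	0	0	1	0	0
P18	missense	1	1	1	0	1	1	0
P19	missense	1	1	1	1	0	1	0
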