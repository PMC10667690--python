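genotype	condition	selection_index	germ21_blup_pct	remarks
Afaa Mwanza 1/159	anaerobic	46	75	Entry
Ciherang Sub1 AG1 AG2	anaerobic	43	79	Check
Rojomena 271/10	anaerobic	31	74	Entry
Kubwa jinga	anaerobic	30	71	Entry
Wahiwahi	anaerobic	28	86	Entry
Magongo ya Wayungu	anaerobic	28	75	Entry
Mpaka wa bibi	anaerobic	26	80	Entry
Mwangaza	anaerobic	26	71	Entry
Tarabinzona	anaerobic	25	80	Entry
IB126-Bug 2013a	anaerobic	25	70	Entry
Kanamalia	anaerobic	25	73	Entry
Iron	aerobic	116.59	92	Entry
Mwangaza	aerobic	78.65	95	Entry
IR15T1302	aerobic	50.82	97	Entry
Tunduru	aerobic	50.70	100	Entry
Ciherang Sub1 AG1	aerobic	45.51	100	Check
Line-8A-2	aerobic	37.61	100	Entry
NERICA 2	aerobic	36.96	100	Entry
Afaa melela	aerobic	33.61	100	Entry
IR16T1339	aerobic	32.97	95	Entry
Lunyuki	aerobic	32.32	100	Entry
Mbega	aerobic	30.30	100	Entry
NERICA 4	aerobic	29.00	100	Entry
Line-18-Niwur1	aerobic	28.83	100	Entry
Kaling'anaula	aerobic	28.12	100	Entry
Swarna Sub1	aerobic	27.54	100	Check
Afaa Mwanza 1/159	across	56	84	Entry
Ciherang Sub1 AG1 AG2	across	54	85	Check
Kanamalia	across	41	82	Entry
Rojomena 271/10	across	39	83	Entry
Kaling'anaula	across	39	80	Entry
Chimdima	across	36	81	Entry
Pishori-Brown	across	34	81	Entry
Gigante	across	33	82	Entry
Tarabinzona	across	28	84	Entry
Faya dume 3	across	28	82	Entry
Faya dume 1	across	26	83	Entry
Tosa	across	26	81	Entry
Magongo ya Wayungu	across	25	83	Entry
Ringa	across	25	81	Entry
Mpaka wa bibi	across	25	84	Entry
IB126-Bug 2013a	across	25	81	Entry
Kivuli	across	25	80	Entry
Mzungu	across	25	81	Entry
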