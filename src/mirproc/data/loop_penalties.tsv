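loop_type	size	dg37_kcal_mol
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
hairpin	10	6.51
hairpin	11	6.62
hairpin	12	6.71
hairpin	13	6.80
hairpin	14	6.88
hairpin	15	6.95
hairpin	16	7.02
hairpin	17	7.09
hairpin	18	7.15
hairpin	19	7.21
hairpin	20	7.26
hairpin	21	7.31
hairpin	22	7.36
hairpin	23	7.41
hairpin	24	7.46
hairpin	25	7.50
hairpin	26	7.54
hairpin	27	7.58
hairpin	28	7.62
hairpin	29	7.66
hairpin	30	7.70
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
bulge	7	4.57
bulge	8	4.71
bulge	9	4.84
bulge	10	4.95
bulge	11	5.05
bulge	12	5.15
bulge	13	5.23
bulge	14	5.31
bulge	15	5.39
bulge	16	5.46
bulge	17	5.52
bulge	18	5.58
bulge	19	5.64
bulge	20	5.70
bulge	21	5.75
bulge	22	5.80
bulge	23	5.85
bulge	24	5.89
bulge	25	5.94
bulge	26	5.98
bulge	27	6.02
bulge	28	6.06
bulge	29	6.10
bulge	30	6.13
internal	2	1.50
internal	3	1.80
internal	4	1.70
internal	5	2.00
internal	6	2.00
internal	7	2.17
internal	8	2.31
internal	9	2.44
internal	10	2.55
internal	11	2.65
internal	12	2.75
internal	13	2.83
internal	14	2.91
internal	15	2.99
internal	16	3.06
internal	17	3.12
internal	18	3.18
internal	19	3.24
internal	20	3.30
internal	21	3.35
internal	22	3.40
internal	23	3.45
internal	24	3.49
internal	25	3.54
internal	26	3.58
internal	27	3.62
internal	28	3.66
internal	29	3.70
internal	30	3.73
multiloop_offset	0	3.40
multiloop_branch	0	0.40
multiloop_unpaired	0	0.10
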