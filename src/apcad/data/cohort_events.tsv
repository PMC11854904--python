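group	type	n_maternal	n_paternal	concordant_gain	concordant_loss	apcad_only
de_novo	BPH trisomy autosome	56	1	1	0	0
de_novo	BPH trisomy XXY	3	2	1	0	0
de_novo	BPH segmental CN gain autosome	1	0	1	0	0
de_novo	BPH segmental CN gain and deletion on autosome	1	0	1	1	0
de_novo	Monosomy autosome	53	3	0	1	0
de_novo	Monosomy X	0	6	0	1	0
de_novo	Deletion on autosome	2	23	0	1	0
de_novo	Deletion on X	1	0	0	1	0
inherited	BPH tetrasomy autosome	1	0	1	0	0
inherited	BPH trisomy autosome	2	0	1	0	0
inherited	BPH segmental CN gain autosome	2	0	1	0	0
inherited	Monosomy autosome	1	0	0	1	0
inherited	Deletion on autosome	2	0	0	1	0
discordant	BPH CN gain 17q (one vs two extra copies)	1	0	1	0	0
discordant	Low-grade BPH CN gain 1q23.3-q24.2 (~6 Mb)	1	0	0	0	1
discordant	Deletion 10q23.1-10q24.31 within mosaic loss of chr10	0	1	0	0	1
discordant	Deletion pter-3p24.2 within mosaic loss of chr3	0	1	0	0	1
discordant	Deletion 17q12-qter within mosaic loss of chr17	0	1	0	1	0
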