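224-414	F224_fa	0	0	1	1
224-414	F224_mo	0	0	2	1
224-414	F224_p1	F224_fa	F224_mo	1	2	MMC
224-414	F224_p2	F224_fa	F224_mo	1	2	MMC
3646	3646_fa	0	0	1	1
3646	3646_mo	0	0	2	2	myelocele
3646	3646_p1	3646_fa	3646_mo	2	2	MMC
3646	3646_s1	3646_fa	3646_mo	1	1
3646	3646_c1	0	0	1	2	myelocele
25	25_fa	0	0	1	1
25	25_mo	0	0	2	1
25	25_p1	25_fa	25_mo	1	2	MMC
260	260_fa	0	0	1	1
260	260_mo	0	0	2	1
260	260_p1	260_fa	260_mo	1	2	MMC
270	270_fa	0	0	1	1
270	270_mo	0	0	2	1
270	270_p1	270_fa	270_mo	1	2	MMC
270	270_p2	270_fa	270_mo	1	2	anencephaly
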