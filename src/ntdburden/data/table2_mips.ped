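M10179	10179	0	0	0	2	NTD
M10194	10194	0	0	0	2	NTD
M10278	10278	0	0	0	2	NTD
M10190	10190	0	0	0	2	NTD
M10322	10322	0	0	0	2	NTD
M20871	20871	0	0	0	1	control
M20785	20785	0	0	0	1	control
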