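W201	201	0	0	0	2	NTD
W265	265	0	0	0	2	NTD
W553	553	0	0	0	2	NTD
W28	28	0	0	0	2	NTD
W552	552	0	0	0	2	NTD
W389	389	0	0	0	2	NTD
W574	574	0	0	0	1	control
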