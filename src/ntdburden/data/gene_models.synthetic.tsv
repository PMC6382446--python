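# Synthetic stand-in gene coding models: real symbols/transcripts with
# approximate coding lengths (bp). Lengths cancel in the two-cohort burden
# comparison, so only their order of magnitude matters here.
symbol	transcript	coding_length
MTHFR	NM_005957.4	1971
DLC1	NM_006094.4	4572
ITGB1	NM_133376.2	2397
APAF1	NM_181868.1	3750
SHROOM3	NM_020859.4	5991
MYO1E	NM_004998.3	3327
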