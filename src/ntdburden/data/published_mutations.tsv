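gene	cdna_change
SHROOM3	c.1320C>T
PAX3
GRHL3
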