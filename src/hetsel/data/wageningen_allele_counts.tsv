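allele	count
het-c1	17
het-c2	51
het-c3	16
het-c4	0
het-c5	17
het-c6	6
het-c7	1
het-c8	1
het-c9	1
het-c10	0
het-c11	0
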