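allele	het-d1	het-d2	het-e1	het-e2	het-e3
het-c1	0	0	0	1	1
het-c2	1	0	1	0	0
het-c3	0	0	0	1	0
het-c4	1	1	0	1	1
het-c5	0	0	0	1	1
het-c6	0	0	0	1	0
het-c7	1	1	1	0	0
het-c8	1	0	1	1	1
het-c9	1	0	0	1	1
het-c10	1	1	0	1	1
het-c11	1	1	0	1	1
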