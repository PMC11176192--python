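category	mechanism	n_clnm	n_total
RET_fusion	fusion	52	73
other_RTK_fusion	fusion	41	64
other_fusion	fusion	4	39
BRAF_mutation	mutation	73	194
other_mutation	mutation	3	58
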