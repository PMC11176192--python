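partner_group	parent_category	n_clnm	n_total
NCOA4_RET	RET_fusion	12	15
CCDC6_RET	RET_fusion	26	40
other_RET_partner	RET_fusion	14	18
NTRK1	other_RTK_fusion	11	13
other_RTK	other_RTK_fusion	30	51
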