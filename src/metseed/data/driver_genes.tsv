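gene	mechanism	provenance
BRAF	mutation	recurrent thyroid carcinoma driver
NRAS	mutation	recurrent thyroid carcinoma driver
HRAS	mutation	recurrent thyroid carcinoma driver
KRAS	mutation	recurrent thyroid carcinoma driver
TP53	mutation	cancer gene census
AKT1	mutation	cancer gene census
PIK3CA	mutation	cancer gene census
PTEN	mutation	cancer gene census
DICER1	mutation	recurrent thyroid carcinoma driver
EIF1AX	mutation	recurrent thyroid carcinoma driver
TSHR	mutation	recurrent thyroid carcinoma driver
GNAS	mutation	recurrent thyroid carcinoma driver
RET	fusion	receptor tyrosine kinase fusion driver
NTRK1	fusion	receptor tyrosine kinase fusion driver
NTRK3	fusion	receptor tyrosine kinase fusion driver
ALK	fusion	receptor tyrosine kinase fusion driver
LTK	fusion	receptor tyrosine kinase fusion driver
MET	fusion	receptor tyrosine kinase fusion driver
FGFR2	fusion	receptor tyrosine kinase fusion driver
BRAF	fusion	kinase fusion driver
PPARG	fusion	transcription factor fusion driver
THADA	fusion	thyroid adenoma associated fusion driver
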