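gene	direction
AR	pos
TMPRSS2	pos
NKX3-1	pos
PIP	pos
CLDN8	pos
FOXA1	pos
SPDEF	pos
APOD	pos
ALCAM	pos
AGR2	pos
DHCR24	pos
ABCC11	pos
UGT2B28	pos
SEC14L2	pos
KRT5	neg
KRT6A	neg
KRT6B	neg
SFRP1	neg
CDH3	neg
TRIM29	neg
GABRP	neg
VIM	neg
EGFR	neg
CAV1	neg
CAV2	neg
MSN	neg
ID4	neg
ELF5	neg
SLPI	neg
S100A8	neg
S100A9	neg
IL6	neg
FABP7	neg
CX3CL1	neg
SOX10	neg
FOXC1	neg
BCL11A	neg
SERPINB5	neg
TP63	neg
DST	neg
COL17A1	neg
LAMB3	neg
LAMC2	neg
PTX3	neg
MMP7	neg
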