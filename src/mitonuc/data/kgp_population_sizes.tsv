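pop	group	n
ESN	Africa	99
GWD	Africa	113
LWK	Africa	99
MSL	Africa	85
YRI	Africa	108
CDX	EastAsia	93
CHB	EastAsia	103
CHS	EastAsia	105
JPT	EastAsia	104
KHV	EastAsia	99
CEU	Europe	99
FIN	Europe	99
GBR	Europe	91
IBS	Europe	107
TSI	Europe	107
BEB	India	86
GIH	India	103
ITU	India	102
PJL	India	96
STU	India	102
ACB	America	96
ASW	America	61
CLM	America	94
MXL	America	64
PEL	America	85
PUR	America	104
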