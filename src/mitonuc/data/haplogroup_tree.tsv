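parent	child	variants	origin	macro
-	reference		Africa	L
reference	L0	263:G,1048:T,3516:A	Africa	L0
reference	L1	3666:A,7055:G	Africa	L1
reference	L5	459:C,7972:T	Africa	L5
reference	L2	2416:C,8206:A	Africa	L2
reference	L3'4	182:T,4104:G	Africa	L3
L3'4	L4	5460:A,6146:G	Africa	L4
L3'4	L3	769:A,1018:A	Africa	L3
L3	M	489:C,10400:T,14783:C	EastAsia	M
L3	N	8701:G,9540:C,10398:G	EastAsia	N
M	D	4883:T,5178:A	EastAsia	M
M	G	4833:G,8200:C	EastAsia	M
N	A	1736:G,4248:C	NativeAmerica	N
N	R	12705:T,16223:C	Europe	R
R	R0	2706:G,11719:A	Europe	R
R0	HV	14766:T	Europe	R
HV	H	2581:G,7028:C	Europe	R
R	U	11467:G,12308:G	Europe	R
U	K	1811:G,9055:A	Europe	R
R	JT	4216:C,11251:G	Europe	R
JT	T	709:A,13368:A	Europe	R
JT	J	12612:G,13708:A	Europe	R
R	B	16189:C	NativeAmerica	R
B	B2	4977:C	NativeAmerica	R
R	R9	3970:T	EastAsia	R
R9	F	6392:C,10310:A	EastAsia	R
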