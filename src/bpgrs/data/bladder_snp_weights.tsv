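rsid	gene	effect_allele	other_allele	eaf	or	ln_or
rs1014971	CBX6/APOBEC3A	T	C	0.656	1.18	0.165514
rs10775480	SLC14A2	T	C	0.455	1.13	0.122218
rs10936599	ACTRT3/MYNN/TERC/LRRC34	C	T	0.742	1.15	0.139762
rs11892031	UGT1A8/UGT1A10	A	C	0.919	1.17	0.157004
rs1495741	NAT2	A	G	0.727	1.13	0.122218
rs17674580	SLC14A1	T	C	0.369	1.17	0.157004
rs2294008	JRK/PSCA	T	C	0.424	1.13	0.122218
rs2736098	TERT	A	G	0.313	1.16	0.14842
rs401681	TERT/CLPTM1L	C	T	0.578	1.12	0.113329
rs4907479	NR	A	G	0.278	1.13	0.122218
rs6104690	C20orf187/LOC339593	A	G	0.424	1.07	0.067659
rs62185668	JAG1	A	C	0.258	1.19	0.173953
rs710521	TP63	A	G	0.702	1.18	0.165514
rs7238033	SLC14A1	C	T	0.455	1.2	0.182322
rs798766	TMEM129/TACC3/FGFR3	T	C	0.793	1.2	0.182322
rs8102137	CCNE1	C	T	0.288	1.13	0.122218
rs907611	LSP	A	G	0.333	1.15	0.139762
rs9642880	MYC/BC042052/CASC11	T	G	0.409	1.21	0.19062
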