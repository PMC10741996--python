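DISULFIDPTOSIS	synthetic stand-in prior set, 84 genes with validated/screened/deduced confidence tiers	SLC7A11	SLC3A2	NCKAP1	RPN1	NUBPL	NDUFA11	LRPPRC	OXSM	NDUFS1	GYS1	SLC2A1	PGD	TKT	TALDO1	GAPDH	GSR	ACTB	ACTN1	ACTN4	ACTR2	ACTR3	ABI2	ANLN	ARPC1B	ARPC2	ARPC3	ARPC4	ARPC5	BRK1	CAPZA1	CAPZA2	CAPZB	CD2AP	CDC42	CFL1	CFL2	CORO1A	CYFIP1	CYFIP2	DIAPH1	DIAPH3	DSTN	EZR	FLNA	FLNB	FMNL2	FSCN1	GSN	IQGAP1	INF2	LIMK1	LIMK2	MSN	MYH9	MYH10	MYH14	MYL6	MYL12A	MYL12B	NCK1	NCK2	NCKAP1L	PDLIM1	PFN1	PXN	RAC1	RDX	RHOA	SSH1	TLN1	TPM1	TPM3	TPM4	VCL	WASF1	WASF2	WASF3	WASL	WIPF1	ZYX	TXN	TXNRD1	GCLC	GCLM
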