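SLC7A11	validated
SLC3A2	validated
NCKAP1	validated
RPN1	validated
NUBPL	screened
NDUFA11	screened
LRPPRC	screened
OXSM	screened
NDUFS1	screened
GYS1	screened
SLC2A1	screened
PGD	screened
TKT	screened
TALDO1	screened
GAPDH	screened
GSR	screened
ACTB	deduced
ACTN1	deduced
ACTN4	deduced
ACTR2	deduced
ACTR3	deduced
ABI2	deduced
ANLN	deduced
ARPC1B	deduced
ARPC2	deduced
ARPC3	deduced
ARPC4	deduced
ARPC5	deduced
BRK1	deduced
CAPZA1	deduced
CAPZA2	deduced
CAPZB	deduced
CD2AP	deduced
CDC42	deduced
CFL1	deduced
CFL2	deduced
CORO1A	deduced
CYFIP1	deduced
CYFIP2	deduced
DIAPH1	deduced
DIAPH3	deduced
DSTN	deduced
EZR	deduced
FLNA	deduced
FLNB	deduced
FMNL2	deduced
FSCN1	deduced
GSN	deduced
IQGAP1	deduced
INF2	deduced
LIMK1	deduced
LIMK2	deduced
MSN	deduced
MYH9	deduced
MYH10	deduced
MYH14	deduced
MYL6	deduced
MYL12A	deduced
MYL12B	deduced
NCK1	deduced
NCK2	deduced
NCKAP1L	deduced
PDLIM1	deduced
PFN1	deduced
PXN	deduced
RAC1	deduced
RDX	deduced
RHOA	deduced
SSH1	deduced
TLN1	deduced
TPM1	deduced
TPM3	deduced
TPM4	deduced
VCL	deduced
WASF1	deduced
WASF2	deduced
WASF3	deduced
WASL	deduced
WIPF1	deduced
ZYX	deduced
TXN	deduced
TXNRD1	deduced
GCLC	deduced
GCLM	deduced
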