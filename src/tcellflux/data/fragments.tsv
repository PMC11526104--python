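# Plausible full-skeleton MOX-TBDMS fragment library (reconstruction;
# the monitored SIM ions of the source study are unpublished).
# columns: fragment_id, metabolite pool, skeleton atoms, ion formula
fragment_id	metabolite	atoms	formula
PYR_full	PYR.obs	1,2,3	C9H18NO3Si
LAC_full	LAC.c	1,2,3	C11H25O3Si2
ALA_full	ALA.c	1,2,3	C11H26NO2Si2
MAL_full	MAL.m	1,2,3,4	C18H39O5Si3
ASP_full	ASP.m	1,2,3,4	C18H40NO4Si3
GLU_full	GLU.m	1,2,3,4,5	C19H42NO4Si3
GLN_full	GLN.c	1,2,3,4,5	C19H41N2O3Si3
CIT_full	CIT.m	1,2,3,4,5,6	C26H55O7Si4
G3P_full	G3P.c	1,2,3	C15H40O6PSi3
PEP_full	PEP.c	1,2,3	C12H26O6PSi2
PG3_full	PG3.c	1,2,3	C17H42O7PSi3
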