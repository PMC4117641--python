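gene	p_value	direction	direct_interactor
MOB4	0.003	larger	True
PSMA1	0.014	smaller	False
TCP1	0.014	larger	True
NOP56	0.014	smaller	False
CCT8	0.015	larger	True
ACTB	0.018	larger	False
RPL10L	0.033	smaller	False
RPL9	0.058	smaller	False
ATP6V1B2	0.064	smaller	False
HSPA8	0.065	larger	False
RPL22	0.087	smaller	False
PSMB3	0.089	smaller	False
RPL11	0.097	smaller	False
RPS13	0.12	smaller	False
PSMC2	0.131	smaller	False
PSMD1	0.137	smaller	False
PRPF8	0.141	smaller	True
ACTR2	0.153	larger	False
ACTG1	0.159	larger	True
PLRG1	0.168	smaller	False
SCFD1	0.189	smaller	False
AP1M1	0.196	smaller	False
RRP15	0.199	larger	False
U2AF1	0.199	smaller	False
RPS12	0.233	smaller	False
SNW1	0.253	larger	False
RPSA	0.272	smaller	False
ARCN1	0.289	smaller	False
SCD	0.289	larger	False
ATP5B	0.299	larger	False
RPS19	0.31	smaller	False
RPS16	0.313	smaller	False
DARS	0.314	smaller	False
RPL8	0.322	smaller	False
STX5	0.33	smaller	False
POLR2A	0.331	smaller	False
GSPT2	0.333	larger	False
EIF3G	0.334	larger	False
DNAJC3	0.343	smaller	False
PSMC5	0.346	smaller	True
CPSF2	0.362	smaller	False
SEC23B	0.371	larger	False
RAB1A	0.382	smaller	False
SF3B1	0.421	smaller	False
PRKAR1A	0.435	smaller	False
RPS3	0.437	smaller	False
OGDHL	0.449	larger	False
SNRPD3	0.458	smaller	False
ACSF2	0.467	larger	False
NDUFA6	0.486	larger	False
UBA6	0.515	larger	False
CRNKL1	0.535	larger	False
MAT1A	0.539	smaller	False
RPL36AL	0.55	larger	False
ATP6V1A	0.557	larger	False
SERINC1	0.577	larger	False
EIF2B5	0.58	smaller	False
HIST1H2BA	0.58	smaller	False
AP1S2	0.655	smaller	False
ATP6V0C	0.759	larger	False
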