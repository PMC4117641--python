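# Human orthologues of the Abeta-paralysis suppressor screen hits (63 symbols)
ACSF2
ACTB
ACTG1
ACTR2
AP1M1
AP1S2
ARCN1
ATP5B
ATP6V0C
ATP6V1A
ATP6V1B2
CCT8
CPSF2
CRNKL1
DARS
DNAJC3
EIF2B5
EIF3G
ELOVL3
GSPT2
HIST1H2BA
HSPA8
MAT1A
MOB4
NDUFA6
NOP56
OGDHL
PLRG1
POLR2A
PREB
PRKAR1A
PRPF8
PSMA1
PSMB3
PSMC2
PSMC5
PSMD1
RAB1A
RPL10L
RPL11
RPL22
RPL36AL
RPL8
RPL9
RPS12
RPS13
RPS16
RPS19
RPS3
RPSA
RRP15
SCD
SCFD1
SEC23B
SERINC1
SF3B1
SNRPD3
SNRPF
SNW1
STX5
TCP1
U2AF1
UBA6
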