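# C. elegans genes whose RNAi knock-down suppresses Abeta-induced paralysis (n = 78)
F46E10.1
T04C12.6
T25C8.2
K07C5.1
F55A12.7
F29G9.3
C13B9.3
C34E10.6
R10E11.8
Y49A3A.2
F20B6.2
Y55F3AR.3
F09G2.4
M03F8.3
B0464.1
C55B6.2
D2085.3
F22B5.2
C40H1.4
H19N07.1
T10C6.11
F26D10.3
C49F5.1
C30A5.3
Y57G11C.12
K07C5.4
T22B11.5
D1054.15
F36A4.7
K02B12.3
R07E4.6
C50C3.6
CD4.6
Y38A8.2
C52E4.4
Y49E10.1
C23G10.4
C39F7.4
F10B5.1
T22F3.4
C27A2.2
C09H10.2
B0250.1
R13A5.8
F54E7.2
C16A3.9
T01C3.6
T05F1.3
C23G10.3
B0393.1
F53E10.6
VZK822L.1
F43D9.3
Y113G7A.3
Y57E12AL.1
T08A11.2
Y116A8C.42
ZK652.1
T27F2.1
F55A11.2
T05C12.7
Y116A8C.35
C47E12.5
C46G7.1
F28C6.7A
Y105E8C.E
K04E7.2
F58G6.7
ZK858.1
Y41D4B.19
F42D1.3
F55C5.4
F17C8.5
C41C4.7A
W09B6.1
D2024.1
W06H8.8
F25B5.4
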