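# C. elegans genes whose RNAi knock-down enhances Abeta-induced paralysis (n = 3)
W02B8.3
F08E10.7
F35A5.3
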