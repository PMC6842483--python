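gene	n_AU	n_DD	literature_direction
PRAME	19	0	up
NPM1	40	0	up
SOX2	303	0	up
NFASC	44	0	up
MYCN	24	0	up
EHF	24	0	up
FAM60A	96	0	up
CD274	48	0	up
FGFR1	113	0	up
STK11	12	33	down
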