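# Stand-in reference list of 10 well-known tumor suppressor genes, used
# to calibrate the DDG thresholds on real cohorts.  Synthetic/stand-in
# curation, not a reproduction of any published supplementary list.
TP53
RB1
PTEN
CDKN2A
APC
SMAD4
BRCA1
BRCA2
NF1
STK11
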