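# Stand-in reference list of 30 well-known oncogenes, one symbol per
# line, used to calibrate the AUG thresholds on real cohorts.  This is a
# synthetic/stand-in curation of popular oncogenes, not a reproduction of
# any published supplementary list; replace with your own list for a
# specific study.
MYC
KRAS
EGFR
ERBB2
MDM2
CCND1
CDK4
CDK6
AKT1
AKT2
PIK3CA
BRAF
MET
ALK
RET
ABL1
SRC
JUN
FOS
MYCN
MYCL
NRAS
HRAS
KIT
PDGFRA
FGFR1
FGFR2
CDK9
MCL1
BCL2
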