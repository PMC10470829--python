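# Default shortlist gene vocabulary: genes recurrently rearranged or
# focally altered in B-cell ALL (mandatory subgroups, UKALL-CNA loci, and
# emerging-subgroup genes).  Coordinates are supplied at run time via a
# BED file for the genome in use; this file fixes only the vocabulary.
ETV6
RUNX1
TCF3
PBX1
KMT2A
BCR
ABL1
ABL2
PDGFRB
PDGFRA
CSF1R
RANBP2
PAX5
CRLF2
P2RY8
IGH
IGK
ZNF384
TAF15
MEF2D
BCL9
ID4
IKZF1
NOL4L
ZCCHC7
SNTA1
DACH2
ARHGAP22
ERG
FUS
EBF1
CDKN2A
CDKN2B
RB1
BTG1
DUX4
KMT2C
AFF1
AFDN
CCDC26
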