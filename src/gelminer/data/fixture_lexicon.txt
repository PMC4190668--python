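# Small gene-symbol lexicon for tests and demos (one symbol per line).
# Production runs should point at a full Entrez Gene symbol export.
LOX
ACTB
actin
GAPDH
TP53
p53
MYC
EGFR
ERBB2
KRAS
BRAF
AKT1
PTEN
RB1
CDK2
CDK4
CCND1
MDM2
BCL2
BAX
CASP3
CASP9
PARP1
STAT3
JAK2
MAPK1
MAPK3
ERK1
ERK2
JNK1
FOS
JUN
NFKB1
RELA
HIF1A
VEGFA
TNF
IL6
IL1B
TGFB1
SMAD2
SMAD3
SMAD4
CTNNB1
GSK3B
mTOR
RPS6
EIF4E
HSP90
HSPA1A
tubulin
TUBB
LMNB1
VIM
CDH1
protein
DNA
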