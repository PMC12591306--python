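# Genes where loss of function drives myeloid malignancy; truncating
# variants in these genes satisfy ARCH-PD criterion C1.
NF1
DNMT3A
TET2
IKZF1
RAD21
WT1
KMT2D
SH2B3
TP53
CEBPA
ASXL1
RUNX1
BCOR
KDM6A
STAG2
PHF6
KMT2C
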