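gene	residue	note
CBL	366	linker/RING hotspot region (seed entry; table is incomplete)
CBL	381	RING finger hotspot (seed entry)
CBL	420	RING finger hotspot (seed entry)
DNMT3A	882	R882 methyltransferase hotspot
FLT3	835	D835 tyrosine-kinase-domain hotspot
FLT3	836	I836 tyrosine-kinase-domain hotspot
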