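precursor_id	species	family	accession
Human GnIH precursor	Homo sapiens	GnIH	NP_071433.3
Quail GnIH precursor	Coturnix japonica	GnIH	XP_015709159.1
Newt LPXRFa precursor	Cynops pyrrhogaster	GnIH	BAJ78290.1
Coelacanth LPXRFa precursor	Latimeria chalumnae	GnIH	XP_005993154.1
Zebrafish LPXRFa precursor	Danio rerio	GnIH	NP_001076418.1
Gar LPXRFa precursor	Lepisosteus oculatus	GnIH	XP_015213317.1
Lamprey LPXRFa precursor	Petromyzon marinus	GnIH	BAL52329.1
Amphioxus RFa precursor	Branchiostoma japonicum	GnIH	BAO77760.1
Human NPFF precursor isoform 1	Homo sapiens	NPFF	NP_003708.1
Human NPFF precursor isoform 2	Homo sapiens	NPFF	NP_001307225.1
Quail NPFF precursor	Coturnix japonica	NPFF	XP_015705838.1
Turtle NPFF precursor	Chrysemys picta bellii	NPFF	XP_005307776.1
Zebrafish NPFF precursor	Danio rerio	NPFF	BAF34891.1
Gar NPFF precursor isoform 2	Lepisosteus oculatus	NPFF	XP_015199730.1
Lamprey PQRFa precursor	Petromyzon marinus	NPFF	BAE79779.1
Lancelet RFa precursor 1	Branchiostoma floridae	NPFF	XP_002599251.1
Lancelet RFa precursor 2	Branchiostoma floridae	NPFF	XP_002609543.1
Fruit fly FMRFamide precursor	Drosophila melanogaster	FMRFamide	NP_523669.2
FLP-1 precursor	Caenorhabditis elegans	FLP	AAC46464.1
FLP-2 precursor	Caenorhabditis elegans	FLP	NP_001024945.1
FLP-3 precursor	Caenorhabditis elegans	FLP	AAC08940.1
FLP-4 precursor	Caenorhabditis elegans	FLP	AAC08941.1
FLP-5 precursor	Caenorhabditis elegans	FLP	AAC08942.1
FLP-6 precursor	Caenorhabditis elegans	FLP	AAC08943.1
FLP-7 precursor	Caenorhabditis elegans	FLP	AAC08944.1
FLP-8 precursor	Caenorhabditis elegans	FLP	AAC08945.1
FLP-9 precursor	Caenorhabditis elegans	FLP	AAC08946.1
FLP-10 precursor	Caenorhabditis elegans	FLP	AAC08947.1
FLP-11 precursor	Caenorhabditis elegans	FLP	NP_001024752.1
FLP-12 precursor	Caenorhabditis elegans	FLP	AAC08950.1
FLP-13 precursor	Caenorhabditis elegans	FLP	AAC08951.1
FLP-14 precursor	Caenorhabditis elegans	FLP	NP_499682.2
FLP-15 precursor	Caenorhabditis elegans	FLP	NP_499820.1
FLP-16 precursor	Caenorhabditis elegans	FLP	NP_001022091.1
FLP-17 precursor	Caenorhabditis elegans	FLP	NP_503051.1
FLP-18 precursor	Caenorhabditis elegans	FLP	NP_508514.2
FLP-19 precursor	Caenorhabditis elegans	FLP	NP_509776.1
FLP-20 precursor	Caenorhabditis elegans	FLP	NP_509574.2
FLP-21 precursor	Caenorhabditis elegans	FLP	NP_505011.2
FLP-22 precursor	Caenorhabditis elegans	FLP	NP_492344.2
FLP-23 precursor	Caenorhabditis elegans	FLP	AAY18633.1
FLP-24 precursor	Caenorhabditis elegans	FLP	AAW78866.1
FLP-25 precursor	Caenorhabditis elegans	FLP	NP_001022665.1
FLP-26 precursor	Caenorhabditis elegans	FLP	NP_741827.1
FLP-27 precursor	Caenorhabditis elegans	FLP	NP_495111.1
FLP-28 precursor	Caenorhabditis elegans	FLP	NP_001024947.1
FLP-32 precursor	Caenorhabditis elegans	FLP	NP_510551.2
FLP-33 precursor	Caenorhabditis elegans	FLP	NP_871818.1
FLP-34 precursor isoform 1	Caenorhabditis elegans	FLP	NP_001300170.1
FLP-34 precursor isoform 2	Caenorhabditis elegans	FLP	NP_503365.1
Hydra insulin-like peptide 2 precursor	Hydra vulgaris	outgroup	ADA67986.1
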