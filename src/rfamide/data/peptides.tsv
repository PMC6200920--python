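peptide_id	sequence	amidated	identified	copy_number	gene_id	species	clade_label	reference_group
Human RFRP-1	MPHSFANLPLRF	true	true	1	Human GnIH precursor	Human	chordate	LRFa
Human RFRP-2	SAGATANLPLRS	true	false	1	Human GnIH precursor	Human	chordate	LRFa
Human RFRP-3	VPNLPQRF	true	true	1	Human GnIH precursor	Human	chordate	PQRFa
Quail GnIH-RP-1	VPNSVANLPLRF	true	false	1	Quail GnIH precursor	Quail	chordate	LRFa
Quail GnIH	SIKPSAYLPLRF	true	true	1	Quail GnIH precursor	Quail	chordate	LRFa
Quail GnIH-RP-2	SSIQSLLNLPQRF	true	true	1	Quail GnIH precursor	Quail	chordate	PQRFa
Newt nLPXRFa-1	SVPNLPQRF	true	true	1	Newt LPXRFa precursor	Newt	chordate	PQRFa
Newt nLPXRFa-2	MPHASANLPLRF	true	true	1	Newt LPXRFa precursor	Newt	chordate	LRFa
Newt nLPXRFa-3	SIQPLANLPQRF	true	true	1	Newt LPXRFa precursor	Newt	chordate	PQRFa
Newt nLPXRFa-4	APSAGQFIQTLANLPQRF	true	true	1	Newt LPXRFa precursor	Newt	chordate	PQRFa
Coelacanth LPXRFa-1	FSNSVINLPLRF	true	false	1	Coelacanth LPXRFa precursor	Coelacanth	chordate	LRFa
Coelacanth LPXRFa-2	LSQSLANLPLRL	true	false	1	Coelacanth LPXRFa precursor	Coelacanth	chordate	LRFa
Coelacanth LPXRFa-3	IPMAIPNLPQRF	true	false	1	Coelacanth LPXRFa precursor	Coelacanth	chordate	PQRFa
Coelacanth LPXRFa-4	SFMQPLANLPQRF	true	false	1	Coelacanth LPXRFa precursor	Coelacanth	chordate	PQRFa
Coelacanth LPXRFa-5	FIQSVANLPQRF	true	false	1	Coelacanth LPXRFa precursor	Coelacanth	chordate	PQRFa
Zebrafish LPXRFa-1	PAHLHANLPLRF	true	false	1	Zebrafish LPXRFa precursor	Zebrafish	chordate	LRFa
Zebrafish LPXRFa-2	STINLPQRF	true	false	1	Zebrafish LPXRFa precursor	Zebrafish	chordate	PQRFa
Zebrafish LPXRFa-3	SGTGPSATLPQRF	true	false	1	Zebrafish LPXRFa precursor	Zebrafish	chordate	PQRFa
Gar LPXRFa-1	LYHSVTNLPLRF	true	false	1	Gar LPXRFa precursor	Gar	chordate	LRFa
Gar LPXRFa-2	ASQPVANLPLRF	true	false	1	Gar LPXRFa precursor	Gar	chordate	LRFa
Gar LPXRFa-3	AALNLPQRF	true	false	1	Gar LPXRFa precursor	Gar	chordate	PQRFa
Lamprey lLPXRFa-1a	SGVGQGRSSKTLFQPQRF	true	true	1	Lamprey LPXRFa precursor	Lamprey	chordate	PQRFa
Lamprey lLPXRFa-2	SEPFWHRTRPQRF	true	true	1	Lamprey LPXRFa precursor	Lamprey	chordate	PQRFa
Amphioxus PQRFa-1	WDEAWRPQRF	true	true	1	Amphioxus PQRFa precursor	Amphioxus	chordate	PQRFa
Amphioxus PQRFa-2	GDHTKDGWRPQRF	true	true	1	Amphioxus PQRFa precursor	Amphioxus	chordate	PQRFa
Amphioxus PQRFa-3	GRDQGWRPQRF	true	true	1	Amphioxus PQRFa precursor	Amphioxus	chordate	PQRFa
FLP-1-1	SADPNFLRF	true	true	1	flp-1	C. elegans	nematode	LRFa
FLP-1-2	SQPNFLRF	true	true	1	flp-1	C. elegans	nematode	LRFa
FLP-1-3	ASGDPNFLRF	true	true	1	flp-1	C. elegans	nematode	LRFa
FLP-1-4	SDPNFLRF	true	true	1	flp-1	C. elegans	nematode	LRFa
FLP-1-5	AAADPNFLRF	true	true	1	flp-1	C. elegans	nematode	LRFa
FLP-1-6	KPNFLRF	true	false	1	flp-1	C. elegans	nematode	LRFa
FLP-1-7	AGSDPNFLRF	true	false	1	flp-1	C. elegans	nematode	LRFa
FLP-1-8	KPNFMRY	true	false	1	flp-1	C. elegans	nematode	MRFa
FLP-2-1	SPREPIRF	true	true	1	flp-2	C. elegans	nematode	IRFa
FLP-2-2	LRGEPIRF	true	false	1	flp-2	C. elegans	nematode	IRFa
FLP-3-1	SPLGTMRF	true	false	1	flp-3	C. elegans	nematode	MRFa
FLP-3-2	TPLGTMRF	true	true	1	flp-3	C. elegans	nematode	MRFa
FLP-3-3	EAEEPLGTMRF	true	true	1	flp-3	C. elegans	nematode	MRFa
FLP-3-4	NPLGTMRF	true	false	1	flp-3	C. elegans	nematode	MRFa
FLP-3-5	ASEDALFGTMRF	true	true	1	flp-3	C. elegans	nematode	MRFa
FLP-3-7	SAEPFGTMRF	true	true	1	flp-3	C. elegans	nematode	MRFa
FLP-3-8	SADDSAPFGTMRF	true	true	1	flp-3	C. elegans	nematode	MRFa
FLP-3-9	NPENDTPFGTMRF	true	true	1	flp-3	C. elegans	nematode	MRFa
FLP-4-1	PTFIRF	true	false	1	flp-4	C. elegans	nematode	IRFa
FLP-4-2	ASPSFIRF	true	false	1	flp-4	C. elegans	nematode	IRFa
FLP-5-1	GAKFIRF	true	true	1	flp-5	C. elegans	nematode	IRFa
FLP-5-2	AGAKFIRF	true	false	1	flp-5	C. elegans	nematode	IRFa
FLP-5-3	APKPKFIRF	true	false	1	flp-5	C. elegans	nematode	IRFa
FLP-6	KSAYMRF	true	true	6	flp-6	C. elegans	nematode	MRFa
FLP-7-1	SPMQRSSMVRF	true	true	3	flp-7	C. elegans	nematode	VRFa
FLP-7-2	TPMQRSSMVRF	true	true	2	flp-7	C. elegans	nematode	VRFa
FLP-7-3	SPMERSAMVRF	true	false	1	flp-7	C. elegans	nematode	VRFa
FLP-7-4	SPMDRSKMVRF	true	false	1	flp-7	C. elegans	nematode	VRFa
FLP-8	KNEFIRF	true	true	3	flp-8	C. elegans	nematode	IRFa
FLP-9	KPSFVRF	true	true	2	flp-9	C. elegans	nematode	VRFa
FLP-10	QPKARSGYIRF	true	false	1	flp-10	C. elegans	nematode	IRFa
FLP-11-1	AMRNALVRF	true	true	1	flp-11	C. elegans	nematode	VRFa
FLP-11-2	ASGGMRNALVRF	true	true	1	flp-11	C. elegans	nematode	VRFa
FLP-11-3	NGAPQPFVRF	true	true	1	flp-11	C. elegans	nematode	VRFa
FLP-12	RNKFEFIRF	true	false	1	flp-12	C. elegans	nematode	IRFa
FLP-13-1	AMDSPLIRF	true	true	1	flp-13	C. elegans	nematode	IRFa
FLP-13-2	AADGAPLIRF	true	true	1	flp-13	C. elegans	nematode	IRFa
FLP-13-3	APEASPFIRF	true	true	2	flp-13	C. elegans	nematode	IRFa
FLP-13-4	ASPSAPLIRF	true	true	1	flp-13	C. elegans	nematode	IRFa
FLP-13-5	SPSAVPLIRF	true	true	1	flp-13	C. elegans	nematode	IRFa
FLP-13-6	ASSAPLIRF	true	false	1	flp-13	C. elegans	nematode	IRFa
FLP-13-7	SAAAPLIRF	true	true	1	flp-13	C. elegans	nematode	IRFa
FLP-14	KHEYLRF	true	true	4	flp-14	C. elegans	nematode	LRFa
FLP-15-1	GGPQGPLRF	true	true	1	flp-15	C. elegans	nematode	LRFa
FLP-15-2	RGPSGPLRF	true	true	1	flp-15	C. elegans	nematode	LRFa
FLP-16-1	AQTFVRF	true	true	2	flp-16	C. elegans	nematode	VRFa
FLP-16-2	GQTFVRF	true	true	1	flp-16	C. elegans	nematode	VRFa
FLP-17-1	KSAFVRF	true	false	3	flp-17	C. elegans	nematode	VRFa
FLP-17-2	KSQYIRF	true	false	1	flp-17	C. elegans	nematode	IRFa
FLP-18-1	DFDGAMPGVLRF	true	false	1	flp-18	C. elegans	nematode	LRFa
FLP-18-2	EMPGVLRF	true	false	1	flp-18	C. elegans	nematode	LRFa
FLP-18-3	SVPGVLRF	true	false	3	flp-18	C. elegans	nematode	LRFa
FLP-18-4	EIPGVLRF	true	false	1	flp-18	C. elegans	nematode	LRFa
FLP-18-5	SEVPGVLRF	true	false	1	flp-18	C. elegans	nematode	LRFa
FLP-18-6	DVPGVLRF	true	false	1	flp-18	C. elegans	nematode	LRFa
FLP-19-1	WANQVRF	true	true	1	flp-19	C. elegans	nematode	VRFa
FLP-19-2	ASWASSVRF	true	true	1	flp-19	C. elegans	nematode	VRFa
FLP-20	AMMRF	true	false	2	flp-20	C. elegans	nematode	MRFa
FLP-21	GLGPRPLRF	true	false	1	flp-21	C. elegans	nematode	LRFa
FLP-22	SPSAKWMRF	true	true	3	flp-22	C. elegans	nematode	MRFa
FLP-23	VVGQQDFLRF	true	false	1	flp-23	C. elegans	nematode	LRFa
FLP-24	VPSAGDMMVRF	true	true	1	flp-24	C. elegans	nematode	VRFa
FLP-25-1	DYDFVRF	true	false	1	flp-25	C. elegans	nematode	VRFa
FLP-25-2	ASYDYIRF	true	true	1	flp-25	C. elegans	nematode	IRFa
FLP-26-1	EFNADDLTLRF	true	true	1	flp-26	C. elegans	nematode	LRFa
FLP-26-2	GGAGEPLAFSPDMLSLRF	true	true	1	flp-26	C. elegans	nematode	LRFa
FLP-27	GLGGRMRF	true	false	1	flp-27	C. elegans	nematode	MRFa
FLP-28	APNRVLMRF	true	true	1	flp-28	C. elegans	nematode	MRFa
FLP-32	AMRNSLVRF	true	false	1	flp-32	C. elegans	nematode	VRFa
FLP-33	APLEGFEDMSGFLRTIDGIQKPRF	true	true	1	flp-33	C. elegans	nematode	LRFa
FLP-34	ALNRDSLVASLNNAERLRF	true	false	1	flp-34	C. elegans	nematode	LRFa
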