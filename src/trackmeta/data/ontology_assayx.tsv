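#name=assayx	version=2021-03-01
iri	label	parents
TESTA:0000001	experimental procedure	
TESTA:0000010	assay	TESTA:0000001
TESTA:0000011	gene-targeted assay	TESTA:0000010
TESTA:0000012	feature-targeted assay	TESTA:0000010
TESTA:0000013	phenotype-targeted assay	TESTA:0000010
TESTA:0000014	untargeted assay	TESTA:0000010
TESTA:0000021	ChIP-seq assay	TESTA:0000011
TESTA:0000022	CUT&RUN assay	TESTA:0000011
TESTA:0000023	DNase-seq assay	TESTA:0000012
TESTA:0000024	ATAC-seq assay	TESTA:0000012
TESTA:0000025	GWAS assay	TESTA:0000013
TESTA:0000026	RNA-seq assay	TESTA:0000014
TESTA:0000027	whole-genome bisulfite sequencing assay	TESTA:0000014
TESTA:0000030	data format	TESTA:0000001
TESTA:0000031	bigWig	TESTA:0000030
TESTA:0000032	bigBed	TESTA:0000030
TESTA:0000033	BED	TESTA:0000030
TESTA:0000034	VCF	TESTA:0000030
TESTA:0000035	bedGraph	TESTA:0000030
TESTA:0000040	biological target	TESTA:0000001
TESTA:0000041	gene product	TESTA:0000040
TESTA:0000042	protein	TESTA:0000041
TESTA:0000043	messenger RNA	TESTA:0000041
TESTA:0000044	macromolecular structure	TESTA:0000040
TESTA:0000045	chromatin loop	TESTA:0000044
TESTA:0000046	nucleosome	TESTA:0000044
TESTA:0000047	sequence feature	TESTA:0000040
TESTA:0000048	transcription factor binding site	TESTA:0000047
TESTA:0000049	open chromatin region	TESTA:0000047
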