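#name=samplex	version=2020-11-15
iri	label	parents
TESTS:0000001	biological entity	
TESTS:0000010	biospecimen	TESTS:0000001
TESTS:0000011	cell line	TESTS:0000010
TESTS:0000012	cell type	TESTS:0000010
TESTS:0000013	abnormal cell type	TESTS:0000010
TESTS:0000014	organism part	TESTS:0000010
TESTS:0000021	H1-hESC	TESTS:0000011
TESTS:0000022	K562	TESTS:0000011
TESTS:0000023	GM12878	TESTS:0000011
TESTS:0000031	B cell, CD19 positive	TESTS:0000012
TESTS:0000032	T cell	TESTS:0000012
TESTS:0000033	monocyte	TESTS:0000012
TESTS:0000041	chronic lymphocytic leukemia cell	TESTS:0000013
TESTS:0000042	acute myeloid leukemia cell	TESTS:0000013
TESTS:0000051	liver	TESTS:0000014
TESTS:0000052	brain	TESTS:0000014
TESTS:0000053	venous blood	TESTS:0000014
TESTS:0000060	phenotype	TESTS:0000001
TESTS:0000061	multiple sclerosis	TESTS:0000060
TESTS:0000062	rheumatoid arthritis	TESTS:0000060
TESTS:0000063	healthy	TESTS:0000060
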