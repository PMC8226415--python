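#name=datausex	version=1.0.2
iri	label	parents
TESTD:0000001	data use condition	
TESTD:0000010	open access	TESTD:0000001
TESTD:0000011	general research use	TESTD:0000010
TESTD:0000012	no restriction	TESTD:0000010
TESTD:0000020	controlled access	TESTD:0000001
TESTD:0000021	disease-specific research	TESTD:0000020
TESTD:0000022	multiple sclerosis research	TESTD:0000021
TESTD:0000023	cancer research	TESTD:0000021
TESTD:0000024	no commercial use	TESTD:0000020
TESTD:0000025	publication moratorium	TESTD:0000020
TESTD:0000026	ethics approval required	TESTD:0000020
TESTD:0000027	collaboration required	TESTD:0000020
TESTD:0000028	genetic studies only	TESTD:0000020
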