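canonical	synonym	scheme	curie
GRCh37	hg19	ucsc	insdc.gca:GCF_000001405.13
GRCh38	hg38	ucsc	insdc.gca:GCF_000001405.26
GRCm38	mm10	ucsc	insdc.gca:GCF_000001635.20
GRCm39	mm39	ucsc	insdc.gca:GCF_000001635.27
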