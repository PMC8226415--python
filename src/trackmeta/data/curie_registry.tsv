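prefix	pattern	url_template
insdc.gca	^GC[AF]_\d{9}\.\d+$	https://example.org/asm/{accession}
taxonomy	^\d+$	https://example.org/taxonomy/{accession}
pubmed	^\d+$	https://example.org/pubmed/{accession}
biosample	^SAM[NED][A-Z]?\d+$	https://example.org/biosample/{accession}
hgnc	^\d+$	https://example.org/hgnc/{accession}
geo	^GS[EM]\d+$	https://example.org/geo/{accession}
ega.experiment	^EGAX\d{11}$	https://example.org/ega/{accession}
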