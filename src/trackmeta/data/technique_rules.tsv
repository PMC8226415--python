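# technique -> target-summary recipe; first matching ancestor wins.
# recipes: gene (gene_id label + ' ' + target_details), sequence_feature,
# phenotype (label of that child), none (empty summary).
ancestor_iri	recipe	status
TESTA:0000011	gene	established
TESTA:0000012	sequence_feature	provisional
TESTA:0000013	phenotype	provisional
TESTA:0000014	none	provisional
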