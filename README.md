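# trackmeta

Exchange tooling for genomic track metadata: a six-object JSON document
model (document info, track collection, study, sample, experiment, track)
with a draft-7 JSON Schema extended by document-set keywords, an extended
validator, a metadata augmenter, and converters between UCSC track-hub
text files, the JSON document model, and a tabular track-collection
format (GSuite dialect).

## What it does

* **model** — typed document model with lossless round-tripping: unknown
  metadata properties anywhere in the document are preserved verbatim.
  `emit_schema()` produces the formal schema, including extension
  keywords (`x_unique`, `x_foreign_ref`, `x_curie_prefixes`,
  `x_ontology_ancestors`, `x_exactly_one_of`) for the checks that plain
  JSON Schema cannot express.
* **registries** — offline stand-ins for identifier/ontology services:
  CURIE prefix registry, DOI syntax, genome-assembly synonym table
  (`hg19` ↔ `GRCh37`), versioned ontology snapshots with label lookup
  and ancestor reachability. Backed by swappable TSV tables
  (`src/trackmeta/data/`).
* **validator** — schema conformance plus uniqueness, foreign-reference
  resolution, aggregation-cycle detection, CURIE checks, ontology
  term/ancestor/label checks, assembly-name consistency, checksum and
  DOI formats, biospecimen-class child rule, and the sample-XOR-upstream
  experiment cardinality rule. Deterministic, error-accumulating report.
* **augmenter** — fills human-readable ontology labels, records the
  ontology versions actually referenced, computes the two merged summary
  fields (`sample_type.summary` by biospecimen class,
  `target.summary` by technique recipe), and stamps `augmented_from`
  provenance. Idempotent and non-destructive.
* **converters** — track-hub import (hub.txt / genomes.txt /
  trackDb.txt stanzas → draft document + curation log) and a tabular
  export/import with a `###`-prefixed header whose first column is the
  track URI.
* **fixtures** — deterministic generators for all test inputs: registry
  bundles, valid documents, rule-isolated invalid documents, and hub
  file sets.

## CLI

```sh
trackmeta validate doc.json             # exit 0 iff clean; --json for JSON
trackmeta augment doc.json -o out.json  # refuses invalid input (--force)
trackmeta convert --to gsuite doc.json  # or --to json export.gsuite
trackmeta import-hub path/to/hub.txt    # draft document + curation log
trackmeta gen-fixture --seed 7 --tracks 5 outdir [--invalid RULE]
trackmeta schema                        # emit the formal schema
```

`-` reads standard input; `--registry-dir` (or a YAML `--config` naming
`registry_dir`) swaps in an alternative registry bundle. Exit codes:
0 ok, 1 validation failure, 2 usage, 3 I/O.

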