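"""Formal schema for the exchange document.

The emitted document is JSON Schema draft 7 augmented with extension
keywords for the checks that plain schema validation cannot express:

``x_unique``
    lists of (object list, field) pairs whose values must be unique.
``x_foreign_ref``
    path pattern -> object list whose local_ids the value must hit.
``x_curie_prefixes``
    path pattern -> allowed registry prefixes ([] = any registered).
``x_ontology_ancestors``
    path pattern -> {ontology, ancestors}: term must exist in the named
    snapshot and descend from every listed IRI.
``x_exactly_one_of``
    object list -> groups of fields of which exactly one must be used.
``x_augmented``
    marks a property as augmentation-owned (filled by the augmenter).
``x_role``
    structural role of each object definition: ``document_info``, the
    ``outer_scope`` grouping object, or a ``key_object`` on the path from
    the document root down to the track-file level.

The same constraint tables drive the validator and the augmenter, so the
schema text and the executable checks cannot drift apart.
"""

from __future__ import annotations

from .model import canonical_dumps

SCHEMA_DIALECT = "http://json-schema.org/draft-07/schema#"

# --- in-schema enumerated vocabularies (replaceable starting points) -------

CONDENSED_DATA_VOCAB = (
    "broad peaks",
    "narrow peaks",
    "gapped peaks",
    "signal intensities",
    "fold change",
    "sequence variants",
    "methylation fraction",
    "gene expression levels",
)

TRACK_TYPE_VOCAB = (
    "points",
    "valued points",
    "segments",
    "valued segments",
    "genome partition",
    "step function",
    "function",
    "linked segments",
)

CHECKSUM_METHODS = ("md5", "sha1", "sha256")
CHECKSUM_LENGTHS = {"md5": 32, "sha1": 40, "sha256": 64}

# --- fixture-registry anchor IRIs used by the constraint tables ------------
# Snapshot names of the packaged registry bundle.
ASSAY_ONTOLOGY = "assayx"
SAMPLE_ONTOLOGY = "samplex"
DATA_USE_ONTOLOGY = "datausex"

ASSAY_CLASS = "TESTA:0000010"
GENE_TARGETED_CLASS = "TESTA:0000011"
FEATURE_TARGETED_CLASS = "TESTA:0000012"
PHENOTYPE_TARGETED_CLASS = "TESTA:0000013"
UNTARGETED_CLASS = "TESTA:0000014"
DATA_FORMAT_CLASS = "TESTA:0000030"
GENE_PRODUCT_CLASS = "TESTA:0000041"
MACROMOL_STRUCTURE_CLASS = "TESTA:0000044"
SEQUENCE_FEATURE_CLASS = "TESTA:0000047"

CELL_LINE_CLASS = "TESTS:0000011"
CELL_TYPE_CLASS = "TESTS:0000012"
ABNORMAL_CELL_TYPE_CLASS = "TESTS:0000013"
ORGANISM_PART_CLASS = "TESTS:0000014"
PHENOTYPE_CLASS = "TESTS:0000060"

DATA_USE_ROOT = "TESTD:0000001"

#: biospecimen_class closed set: term IRI -> (label, owning sample_type child)
BIOSPECIMEN_CLASSES = {
    CELL_LINE_CLASS: ("cell line", "cell_line"),
    CELL_TYPE_CLASS: ("cell type", "cell_type"),
    ABNORMAL_CELL_TYPE_CLASS: ("abnormal cell type", "abnormal_cell_type"),
    ORGANISM_PART_CLASS: ("organism part", "organism_part"),
}

# --- constraint tables ------------------------------------------------------
# (object list, dotted field path within the object, ontology, ancestor IRIs)
# '[]' marks a list-valued field whose elements are term pairs.
TERM_FIELD_CONSTRAINTS = (
    ("samples", "biospecimen_class", SAMPLE_ONTOLOGY, ()),
    ("samples", "sample_type.cell_line", SAMPLE_ONTOLOGY, (CELL_LINE_CLASS,)),
    ("samples", "sample_type.cell_type", SAMPLE_ONTOLOGY, (CELL_TYPE_CLASS,)),
    ("samples", "sample_type.abnormal_cell_type", SAMPLE_ONTOLOGY,
     (ABNORMAL_CELL_TYPE_CLASS,)),
    ("samples", "sample_type.organism_part", SAMPLE_ONTOLOGY,
     (ORGANISM_PART_CLASS,)),
    ("samples", "phenotype", SAMPLE_ONTOLOGY, (PHENOTYPE_CLASS,)),
    ("experiments", "technique", ASSAY_ONTOLOGY, (ASSAY_CLASS,)),
    ("experiments", "target.gene_product_type", ASSAY_ONTOLOGY,
     (GENE_PRODUCT_CLASS,)),
    ("experiments", "target.macromolecular_structure", ASSAY_ONTOLOGY,
     (MACROMOL_STRUCTURE_CLASS,)),
    ("experiments", "target.phenotype", SAMPLE_ONTOLOGY, (PHENOTYPE_CLASS,)),
    ("experiments", "target.sequence_feature", ASSAY_ONTOLOGY,
     (SEQUENCE_FEATURE_CLASS,)),
    ("tracks", "file_format", ASSAY_ONTOLOGY, (DATA_FORMAT_CLASS,)),
    ("tracks", "data_use_conditions[]", DATA_USE_ONTOLOGY, (DATA_USE_ROOT,)),
)

# (object list, dotted field path, allowed prefixes; () = any registered)
CURIE_FIELD_CONSTRAINTS = (
    ("studies", "publications[]", ()),
    ("samples", "species", ("taxonomy",)),
    ("samples", "external_refs[]", ()),
    ("experiments", "target.gene_id", ()),
    ("tracks", "assembly_id", ("insdc.gca",)),
    ("tracks", "raw_file_ids[]", ()),
)

#: object list -> groups of fields of which exactly one must be non-empty
EXACTLY_ONE_OF = {"experiments": (("sample_ref", "aggregated_from"),)}

#: (object list, reference field path) -> referenced object list
FOREIGN_REFS = (
    ("studies", "collection_ref", "collections"),
    ("experiments", "study_ref", "studies"),
    ("experiments", "sample_ref", "samples"),
    ("experiments", "aggregated_from[]", "experiments"),
    ("tracks", "source_coll_ref", "collections"),
    ("tracks", "experiment_ref", "experiments"),
)

UNIQUE_FIELDS = (
    ("collections", "local_id"),
    ("studies", "local_id"),
    ("samples", "local_id"),
    ("experiments", "local_id"),
    ("tracks", "local_id"),
)

_URL_PATTERN = r"^(https?|ftp)://\S+$"
_DATE_PATTERN = r"^\d{4}-\d{2}-\d{2}$"
_EMAIL_PATTERN = r"^[^@\s]+@[^@\s]+$"


def _s(**kwargs):
    return {"type": "string", **kwargs}


def _id():
    return _s(minLength=1)


def _url():
    return _s(pattern=_URL_PATTERN)


def _ref(name):
    return {"$ref": f"#/definitions/{name}"}


def _term_pair_def():
    return {
        "type": "object",
        "required": ["term_id"],
        "properties": {
            "term_id": _id(),
            "term_label": {**_s(), "x_augmented": True},
        },
    }


def build_schema() -> dict:
    """The schema as a plain dict; see :func:`emit_schema` for the text."""
    definitions = {
        "term_pair": _term_pair_def(),
        "contact_info": {
            "type": "object",
            "required": ["name", "email"],
            "properties": {
                "name": _id(),
                "email": _s(pattern=_EMAIL_PATTERN),
                "url": _url(),
            },
        },
        "doc_info": {
            "type": "object",
            "x_role": "document_info",
            "required": ["local_id", "version_id", "version_date",
                         "ontology_versions", "source_url", "doi"],
            "properties": {
                "local_id": _id(),
                "version_id": _id(),
                "version_date": _s(pattern=_DATE_PATTERN),
                "ontology_versions": {
                    "type": "object",
                    "additionalProperties": {"type": "string"},
                    "x_augmented": True,
                },
                "source_url": _url(),
                "doi": _id(),
                "derived_from": _s(),
                "augmented_from": {**_s(), "x_augmented": True},
            },
        },
        "collection": {
            "type": "object",
            "x_role": "outer_scope",
            "required": ["local_id", "name", "description", "source_url",
                         "contact"],
            "properties": {
                "local_id": _id(),
                "name": _id(),
                "description": _s(),
                "source_url": _url(),
                "contact": _ref("contact_info"),
            },
        },
        "study": {
            "type": "object",
            "x_role": "key_object",
            "required": ["local_id", "collection_ref", "name",
                         "publications", "contact"],
            "properties": {
                "local_id": _id(),
                "collection_ref": _id(),
                "name": _id(),
                "publications": {"type": "array", "items": _s()},
                "contact": _ref("contact_info"),
            },
        },
        "sample_type": {
            "type": "object",
            "properties": {
                "cell_type": _ref("term_pair"),
                "cell_line": _ref("term_pair"),
                "abnormal_cell_type": _ref("term_pair"),
                "organism_part": _ref("term_pair"),
                "summary": {**_s(), "x_augmented": True},
            },
        },
        "sample": {
            "type": "object",
            "x_role": "key_object",
            "required": ["local_id", "species", "biospecimen_class",
                         "sample_type"],
            "properties": {
                "local_id": _id(),
                "species": _id(),
                "biospecimen_class": {
                    "allOf": [_ref("term_pair")],
                    "properties": {
                        "term_id": {"enum": sorted(BIOSPECIMEN_CLASSES)},
                    },
                },
                "sample_type": _ref("sample_type"),
                "phenotype": _ref("term_pair"),
                "external_refs": {"type": "array", "items": _s()},
            },
        },
        "target": {
            "type": "object",
            "properties": {
                "gene_id": _ref("term_pair"),
                "gene_product_type": _ref("term_pair"),
                "macromolecular_structure": _ref("term_pair"),
                "phenotype": _ref("term_pair"),
                "sequence_feature": _ref("term_pair"),
                "target_details": _s(),
                "summary": {**_s(), "x_augmented": True},
            },
        },
        "experiment": {
            "type": "object",
            "x_role": "key_object",
            "required": ["local_id", "study_ref", "technique", "target",
                         "lab_protocol_description",
                         "compute_protocol_description"],
            "properties": {
                "local_id": _id(),
                "study_ref": _id(),
                "sample_ref": _s(),
                "aggregated_from": {"type": "array", "items": _s()},
                "technique": _ref("term_pair"),
                "target": _ref("target"),
                "lab_protocol_description": _s(),
                "compute_protocol_description": _s(),
            },
        },
        "checksum": {
            "type": "object",
            "required": ["method", "value"],
            "properties": {
                "method": {"enum": list(CHECKSUM_METHODS)},
                "value": _s(),
            },
        },
        "track": {
            "type": "object",
            "x_role": "key_object",
            "required": ["local_id", "source_coll_ref", "experiment_ref",
                         "file_url", "label_short", "label_long",
                         "description", "assembly_id", "annotation_name",
                         "raw_file_ids", "file_format",
                         "type_of_condensed_data", "genomic_track_type",
                         "checksum"],
            "properties": {
                "local_id": _id(),
                "source_coll_ref": _id(),
                "experiment_ref": _id(),
                "file_url": _url(),
                "label_short": _id(),
                "label_long": _id(),
                "description": _s(),
                "assembly_id": _id(),
                "annotation_name": _id(),
                "raw_file_ids": {"type": "array", "items": _s()},
                "file_format": _ref("term_pair"),
                "type_of_condensed_data": {"enum": list(CONDENSED_DATA_VOCAB)},
                "genomic_track_type": {"enum": list(TRACK_TYPE_VOCAB)},
                "checksum": _ref("checksum"),
                "data_use_conditions": {
                    "type": "array", "items": _ref("term_pair"),
                },
                "data_use_url": _url(),
            },
        },
    }

    def _pattern(list_name: str, dotted: str) -> str:
        path = f"{list_name}/*/" + dotted.replace(".", "/")
        return path.replace("[]", "/*")

    return {
        "$schema": SCHEMA_DIALECT,
        "$id": "https://example.org/schemas/track-metadata-exchange.json",
        "title": "Genomic track metadata exchange document",
        "type": "object",
        "required": ["doc_info", "collections", "studies", "samples",
                     "experiments", "tracks"],
        "properties": {
            "doc_info": _ref("doc_info"),
            "collections": {"type": "array", "items": _ref("collection")},
            "studies": {"type": "array", "items": _ref("study")},
            "samples": {"type": "array", "items": _ref("sample")},
            "experiments": {"type": "array", "items": _ref("experiment")},
            "tracks": {"type": "array", "items": _ref("track")},
        },
        "definitions": definitions,
        "x_unique": [list(pair) for pair in UNIQUE_FIELDS],
        "x_foreign_ref": {
            _pattern(ln, f): target for ln, f, target in FOREIGN_REFS
        },
        "x_curie_prefixes": {
            _pattern(ln, f): list(prefixes)
            for ln, f, prefixes in CURIE_FIELD_CONSTRAINTS
        },
        "x_ontology_ancestors": {
            _pattern(ln, f): {"ontology": ont, "ancestors": list(ancestors)}
            for ln, f, ont, ancestors in TERM_FIELD_CONSTRAINTS
        },
        "x_exactly_one_of": {
            ln: [list(group) for group in groups]
            for ln, groups in EXACTLY_ONE_OF.items()
        },
    }


def emit_schema() -> str:
    """Canonical schema text (a serialization fixed point)."""
    return canonical_dumps(build_schema())
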