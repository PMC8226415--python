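"""The six-object document model and its lossless JSON (de)serialization.

Every object keeps unknown input fields verbatim in its ``extra`` mapping,
so arbitrary metadata properties survive a load/dump round trip.  No
validation happens here; see :mod:`trackmeta.validator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Any

from .errors import ParseError, StructureError


def canonical_dumps(obj: Any) -> str:
    """Deterministic JSON text: sorted keys, UTF-8, newline-terminated."""
    return json.dumps(obj, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def _require_obj(value: Any, path: str) -> dict:
    if not isinstance(value, dict):
        raise StructureError(f"{path}: expected a JSON object, got "
                             f"{type(value).__name__}")
    return value


def _require_list(value: Any, path: str) -> list:
    if not isinstance(value, list):
        raise StructureError(f"{path}: expected a JSON array, got "
                             f"{type(value).__name__}")
    return value


class _Node:
    """Shared (de)serialization machinery for all model dataclasses.

    Subclasses declare ``_nested`` (field name -> node class) and
    ``_list_nested`` (field name -> element node class); every other
    dataclass field is copied verbatim.  Keys not matching any declared
    field land in ``extra``.
    """

    _nested: dict[str, type] = {}
    _list_nested: dict[str, type] = {}

    @classmethod
    def from_obj(cls, obj: dict, path: str = ""):
        _require_obj(obj, path or "/")
        known = {f.name for f in fields(cls)} - {"extra"}
        kwargs: dict[str, Any] = {}
        extra: dict[str, Any] = {}
        for key, value in obj.items():
            if key not in known:
                extra[key] = value
                continue
            here = f"{path}/{key}"
            if key in cls._nested:
                kwargs[key] = (
                    None if value is None
                    else cls._nested[key].from_obj(value, here)
                )
            elif key in cls._list_nested:
                elem_cls = cls._list_nested[key]
                kwargs[key] = [
                    elem_cls.from_obj(v, f"{here}/{i}")
                    for i, v in enumerate(_require_list(value, here))
                ]
            else:
                kwargs[key] = value
        return cls(extra=extra, **kwargs)

    def to_obj(self) -> dict:
        out: dict[str, Any] = {}
        for f in fields(self):
            if f.name == "extra":
                continue
            value = getattr(self, f.name)
            if value is None:
                continue
            if f.name in self._nested:
                out[f.name] = value.to_obj()
            elif f.name in self._list_nested:
                out[f.name] = [v.to_obj() for v in value]
            else:
                out[f.name] = value
        out.update(self.extra)
        return out


@dataclass
class TermPair(_Node):
    """A controlled value: term IRI plus its human-readable label.

    ``term_label`` is augmentation-owned; submitters may omit it.  The same
    two-field shape is reused for gene identifiers, where ``term_id`` holds
    a CURIE and ``term_label`` the submitter-provided gene symbol.
    """

    term_id: str | None = None
    term_label: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ContactInfo(_Node):
    name: str | None = None
    email: str | None = None
    url: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class DocInfo(_Node):
    local_id: str | None = None
    version_id: str | None = None
    version_date: str | None = None
    ontology_versions: dict | None = None
    source_url: str | None = None
    doi: str | None = None
    derived_from: str | None = None
    augmented_from: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class TrackCollection(_Node):
    _nested = {"contact": ContactInfo}

    local_id: str | None = None
    name: str | None = None
    description: str | None = None
    source_url: str | None = None
    contact: ContactInfo | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class Study(_Node):
    _nested = {"contact": ContactInfo}

    local_id: str | None = None
    collection_ref: str | None = None
    name: str | None = None
    publications: list | None = None
    contact: ContactInfo | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class SampleType(_Node):
    _nested = {
        "cell_type": TermPair,
        "cell_line": TermPair,
        "abnormal_cell_type": TermPair,
        "organism_part": TermPair,
    }

    cell_type: TermPair | None = None
    cell_line: TermPair | None = None
    abnormal_cell_type: TermPair | None = None
    organism_part: TermPair | None = None
    summary: str | None = None  # augmentation-owned
    extra: dict = field(default_factory=dict)


@dataclass
class Sample(_Node):
    _nested = {
        "biospecimen_class": TermPair,
        "sample_type": SampleType,
        "phenotype": TermPair,
    }

    local_id: str | None = None
    species: str | None = None
    biospecimen_class: TermPair | None = None
    sample_type: SampleType | None = None
    phenotype: TermPair | None = None
    external_refs: list | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class Target(_Node):
    _nested = {
        "gene_id": TermPair,
        "gene_product_type": TermPair,
        "macromolecular_structure": TermPair,
        "phenotype": TermPair,
        "sequence_feature": TermPair,
    }

    gene_id: TermPair | None = None
    gene_product_type: TermPair | None = None
    macromolecular_structure: TermPair | None = None
    phenotype: TermPair | None = None
    sequence_feature: TermPair | None = None
    target_details: str | None = None
    summary: str | None = None  # augmentation-owned
    extra: dict = field(default_factory=dict)


@dataclass
class Experiment(_Node):
    _nested = {"technique": TermPair, "target": Target}

    local_id: str | None = None
    study_ref: str | None = None
    sample_ref: str | None = None
    aggregated_from: list | None = None
    technique: TermPair | None = None
    target: Target | None = None
    lab_protocol_description: str | None = None
    compute_protocol_description: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class Checksum(_Node):
    method: str | None = None
    value: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class Track(_Node):
    _nested = {"file_format": TermPair, "checksum": Checksum}
    _list_nested = {"data_use_conditions": TermPair}

    local_id: str | None = None
    source_coll_ref: str | None = None
    experiment_ref: str | None = None
    file_url: str | None = None
    label_short: str | None = None
    label_long: str | None = None
    description: str | None = None
    assembly_id: str | None = None
    annotation_name: str | None = None
    raw_file_ids: list | None = None
    file_format: TermPair | None = None
    type_of_condensed_data: str | None = None
    genomic_track_type: str | None = None
    checksum: Checksum | None = None
    data_use_conditions: list | None = None
    data_use_url: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class FairDocument(_Node):
    """The root exchange record: document info plus flat object lists
    cross-linked by local identifiers."""

    _nested = {"doc_info": DocInfo}
    _list_nested = {
        "collections": TrackCollection,
        "studies": Study,
        "samples": Sample,
        "experiments": Experiment,
        "tracks": Track,
    }

    doc_info: DocInfo | None = None
    collections: list = field(default_factory=list)
    studies: list = field(default_factory=list)
    samples: list = field(default_factory=list)
    experiments: list = field(default_factory=list)
    tracks: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_obj(self) -> dict:
        out = super().to_obj()
        # the object lists define the document shape: always present
        for key in ("collections", "studies", "samples", "experiments",
                    "tracks"):
            out.setdefault(key, [])
        return out


def load_document(text: str) -> FairDocument:
    """Parse JSON text into a :class:`FairDocument`; no validation."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(exc.msg, exc.lineno, exc.colno) from exc
    if not isinstance(obj, dict):
        raise StructureError(
            f"top level must be a JSON object, got {type(obj).__name__}"
        )
    return FairDocument.from_obj(obj)


def dump_document(doc: FairDocument) -> str:
    """Serialize to canonical JSON (sorted keys, two-space indent, UTF-8,
    newline-terminated).  ``load_document(dump_document(d)) == d``."""
    return canonical_dumps(doc.to_obj())
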