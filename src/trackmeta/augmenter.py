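"""Augmentation: turn a minimally-filled valid document into a
downstream-friendly one.

Adds human-readable ontology labels, records the ontology versions actually
referenced, computes the two merged summary fields, and stamps document
provenance.  Submitted content is never removed or altered: only absent
label/summary slots are filled, and the augmentation-owned
``ontology_versions`` / ``augmented_from`` fields are (re)written.
Augmentation is idempotent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources

from . import registries as reg
from . import schema as sch
from .errors import (
    AugmentationRefusedError,
    BiospecimenChildMissingError,
    ConfigurationError,
    TargetChildMissingError,
)
from .model import Experiment, FairDocument, Sample
from .validator import DocumentValidator, _iter_constraints

#: summary recipe names -> the target child they read
_RECIPE_CHILDREN = {
    "gene": "gene_id",
    "sequence_feature": "sequence_feature",
    "phenotype": "phenotype",
    "none": None,
}


@dataclass(frozen=True)
class TechniqueRule:
    """One row of the technique->summary recipe table."""

    ancestor_iri: str
    recipe: str
    status: str  # "established" or "provisional"


def load_technique_rules() -> tuple[TechniqueRule, ...]:
    """The packaged recipe table (first matching ancestor wins).

    Shipped as TSV data rather than code so adopters can extend it; only
    the gene-targeted row is an established rule, the rest are provisional.
    """
    text = (
        resources.files("trackmeta") / "data" / "technique_rules.tsv"
    ).read_text(encoding="utf-8")
    rules = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") \
                or line.startswith("ancestor_iri\t"):
            continue
        ancestor, recipe, status = line.split("\t")
        if recipe not in _RECIPE_CHILDREN:
            raise ConfigurationError(f"unknown summary recipe {recipe!r}")
        rules.append(TechniqueRule(ancestor, recipe, status))
    return tuple(rules)


def _label_for(pair, snapshot):
    return pair.term_label if pair.term_label is not None \
        else snapshot.label_of(pair.term_id)


def summarize_sample_type(sample: Sample, snapshots: dict | None = None
                          ) -> str:
    """Merge the sample_type children into one string: the label of the
    child selected by ``biospecimen_class``."""
    cls = sample.biospecimen_class
    if cls is None or cls.term_id not in sch.BIOSPECIMEN_CLASSES:
        raise BiospecimenChildMissingError(
            f"sample {sample.local_id!r}: biospecimen_class missing or "
            f"outside the closed set"
        )
    class_label, child_name = sch.BIOSPECIMEN_CLASSES[cls.term_id]
    child = getattr(sample.sample_type, child_name) \
        if sample.sample_type else None
    if child is None:
        raise BiospecimenChildMissingError(
            f"sample {sample.local_id!r}: biospecimen_class "
            f"{class_label!r} requires the sample_type child {child_name!r}"
        )
    if child.term_label is not None:
        return child.term_label
    if snapshots is not None:
        return snapshots[sch.SAMPLE_ONTOLOGY].label_of(child.term_id)
    raise BiospecimenChildMissingError(
        f"sample {sample.local_id!r}: child {child_name!r} has no label "
        f"and no snapshots were supplied"
    )


def summarize_target(experiment: Experiment,
                     snapshots: dict | None = None,
                     rules: tuple[TechniqueRule, ...] | None = None) -> str:
    """Merge the target children into one string, per the recipe selected
    by the experiment's technique.

    Gene-targeted techniques yield the gene label, followed by a single
    space plus ``target_details`` when non-empty; feature- and
    phenotype-targeted techniques yield the corresponding child's label;
    untargeted techniques (and techniques matching no rule) yield "".
    """
    if snapshots is None:
        snapshots = reg.default_registries().ontologies
    rules = rules if rules is not None else load_technique_rules()
    technique = experiment.technique
    if technique is None or not technique.term_id:
        raise TargetChildMissingError(
            f"experiment {experiment.local_id!r}: no technique"
        )
    snapshot = snapshots[sch.ASSAY_ONTOLOGY]
    recipe = "none"
    for rule in rules:
        if snapshot.is_descendant(technique.term_id, rule.ancestor_iri):
            recipe = rule.recipe
            break
    child_name = _RECIPE_CHILDREN[recipe]
    if child_name is None:
        return ""
    target = experiment.target
    child = getattr(target, child_name) if target is not None else None
    if child is None or child.term_id is None and child.term_label is None:
        raise TargetChildMissingError(
            f"experiment {experiment.local_id!r}: recipe {recipe!r} "
            f"requires target child {child_name!r}"
        )
    if recipe == "gene":
        label = child.term_label
        if label is None:
            raise TargetChildMissingError(
                f"experiment {experiment.local_id!r}: gene_id has no label"
            )
        details = (target.target_details or "").strip()
        return f"{label} {details}" if details else label
    # ontology-backed children: resolve via snapshot when label absent
    constraint = {
        "sequence_feature": sch.ASSAY_ONTOLOGY,
        "phenotype": sch.SAMPLE_ONTOLOGY,
    }[child_name]
    return _label_for(child, snapshots[constraint])


def augment_document(doc: FairDocument,
                     registries: reg.RegistrySet | None = None,
                     force: bool = False) -> FairDocument:
    """Return an augmented deep copy of ``doc``.

    Refuses (raising :class:`AugmentationRefusedError`) unless the input
    passes full validation.  With ``force=True`` validation is skipped and
    fields that cannot be augmented are simply left alone.
    """
    registries = registries or reg.default_registries()
    if not force:
        report = DocumentValidator(registries).validate(doc)
        if not report.ok:
            raise AugmentationRefusedError(report)

    snapshots = registries.ontologies
    out = copy.deepcopy(doc)

    # 1. fill absent ontology labels and collect referenced snapshots
    referenced: set[str] = set()
    for _, pair, ontology, _ancestors in _iter_constraints(
        out, sch.TERM_FIELD_CONSTRAINTS
    ):
        if not pair.term_id:
            continue
        snapshot = snapshots[ontology]
        if pair.term_id not in snapshot:
            continue  # unreachable on validated input
        referenced.add(ontology)
        if pair.term_label is None:
            pair.term_label = snapshot.label_of(pair.term_id)

    # 2. merged summary fields
    rules = load_technique_rules()
    for sample in out.samples:
        if sample.sample_type is None or \
                sample.sample_type.summary is not None:
            continue
        try:
            sample.sample_type.summary = summarize_sample_type(
                sample, snapshots
            )
        except BiospecimenChildMissingError:
            if not force:
                raise
    for experiment in out.experiments:
        if experiment.target is None or \
                experiment.target.summary is not None:
            continue
        try:
            experiment.target.summary = summarize_target(
                experiment, snapshots, rules
            )
        except (TargetChildMissingError, reg.OntologyTermError):
            if not force:
                raise

    # 3. ontology version capture: exactly the snapshots referenced
    out.doc_info.ontology_versions = {
        name: snapshots[name].version for name in sorted(referenced)
    }

    # 4. provenance stamp: DOI preferred over version id
    out.doc_info.augmented_from = doc.doc_info.doi or doc.doc_info.version_id
    return out
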