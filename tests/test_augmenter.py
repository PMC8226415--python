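import pytest

from trackmeta.augmenter import (
    augment_document,
    load_technique_rules,
    summarize_sample_type,
    summarize_target,
)
from trackmeta.errors import (
    AugmentationRefusedError,
    BiospecimenChildMissingError,
    TargetChildMissingError,
)
from trackmeta.fixtures import make_invalid_document, make_valid_document
from trackmeta.model import Experiment, Sample, SampleType, Target, TermPair
from trackmeta.schema import (
    CELL_LINE_CLASS,
    CELL_TYPE_CLASS,
    TERM_FIELD_CONSTRAINTS,
)
from trackmeta.validator import _iter_constraints


def _tree_items(obj, prefix=""):
    """Independent tree walk: (path, value) pairs for all leaves."""
    if isinstance(obj, dict):
        items = set()
        for key, value in obj.items():
            items |= _tree_items(value, f"{prefix}/{key}")
        return items
    if isinstance(obj, list):
        items = set()
        for i, value in enumerate(obj):
            items |= _tree_items(value, f"{prefix}/{i}")
        return items
    return {(prefix, repr(obj))}


AUGMENTATION_OWNED = ("term_label", "summary", "ontology_versions",
                      "augmented_from")


def _owned(path):
    return any(f"/{name}" in path for name in AUGMENTATION_OWNED)


class TestSummarizeSampleType:
    def _sample(self, class_iri, child_name, label):
        sample_type = SampleType()
        if child_name:
            setattr(sample_type, child_name,
                    TermPair(term_id="TESTS:0000021", term_label=label))
        return Sample(local_id="s1", biospecimen_class=TermPair(
            term_id=class_iri), sample_type=sample_type)

    def test_cell_line_rule(self):
        sample = self._sample(CELL_LINE_CLASS, "cell_line", "H1-hESC")
        assert summarize_sample_type(sample) == "H1-hESC"

    def test_cell_type_rule(self):
        sample = self._sample(CELL_TYPE_CLASS, "cell_type",
                              "B cell, CD19 positive")
        assert summarize_sample_type(sample) == "B cell, CD19 positive"

    def test_missing_selected_child(self):
        sample = self._sample(CELL_LINE_CLASS, None, None)
        with pytest.raises(BiospecimenChildMissingError):
            summarize_sample_type(sample)

    def test_label_resolved_from_snapshot_when_absent(self, registries):
        sample = self._sample(CELL_LINE_CLASS, "cell_line", None)
        assert summarize_sample_type(
            sample, registries.ontologies) == "H1-hESC"


class TestSummarizeTarget:
    def _experiment(self, technique_iri, **target_kwargs):
        return Experiment(local_id="e1",
                          technique=TermPair(term_id=technique_iri),
                          target=Target(**target_kwargs))

    def test_gene_targeted_without_details(self, registries):
        exp = self._experiment(
            "TESTA:0000021",
            gene_id=TermPair(term_id="hgnc:13723", term_label="CTCF"))
        assert summarize_target(exp, registries.ontologies) == "CTCF"

    def test_gene_targeted_with_details_joined_by_single_space(
            self, registries):
        exp = self._experiment(
            "TESTA:0000021",
            gene_id=TermPair(term_id="hgnc:13723", term_label="CTCF"),
            target_details="phosphorylated")
        assert summarize_target(
            exp, registries.ontologies) == "CTCF phosphorylated"

    def test_untargeted_yields_empty_string(self, registries):
        exp = self._experiment("TESTA:0000026")  # RNA-seq
        assert summarize_target(exp, registries.ontologies) == ""

    def test_feature_targeted_uses_sequence_feature_label(self, registries):
        exp = self._experiment(
            "TESTA:0000023",
            sequence_feature=TermPair(term_id="TESTA:0000049"))
        assert summarize_target(
            exp, registries.ontologies) == "open chromatin region"

    def test_phenotype_targeted(self, registries):
        exp = self._experiment(
            "TESTA:0000025",
            phenotype=TermPair(term_id="TESTS:0000061"))
        assert summarize_target(
            exp, registries.ontologies) == "multiple sclerosis"

    def test_missing_demanded_child(self, registries):
        exp = self._experiment("TESTA:0000021")  # gene recipe, no gene_id
        with pytest.raises(TargetChildMissingError):
            summarize_target(exp, registries.ontologies)

    def test_rule_table_is_data(self):
        rules = load_technique_rules()
        assert [r.recipe for r in rules] == [
            "gene", "sequence_feature", "phenotype", "none"]
        assert rules[0].status == "established"
        assert all(r.status == "provisional" for r in rules[1:])


class TestAugmentDocument:
    def test_refuses_invalid_input(self, registries):
        doc = make_invalid_document(3, "foreign_ref")
        with pytest.raises(AugmentationRefusedError) as exc:
            augment_document(doc, registries)
        assert "foreign_ref" in str(exc.value)

    def test_force_augments_invalid_input(self, registries):
        doc = make_invalid_document(3, "foreign_ref")
        out = augment_document(doc, registries, force=True)
        assert out.doc_info.augmented_from == doc.doc_info.doi

    def test_all_term_pairs_gain_labels(self, registries, valid_doc):
        out = augment_document(valid_doc, registries)
        for _, pair, _, _ in _iter_constraints(out,
                                               TERM_FIELD_CONSTRAINTS):
            assert pair.term_label is not None

    def test_version_capture_two_of_three_snapshots(self, registries):
        doc = make_valid_document(4)
        for track in doc.tracks:  # remove every data-use term
            track.data_use_conditions = None
            track.data_use_url = None
        out = augment_document(doc, registries)
        assert set(out.doc_info.ontology_versions) == {"assayx", "samplex"}
        assert out.doc_info.ontology_versions["assayx"] == \
            registries.ontologies["assayx"].version

    @pytest.mark.parametrize("seed", range(0, 50, 5))
    def test_version_capture_exactness(self, registries, seed):
        doc = make_valid_document(seed)
        out = augment_document(doc, registries)
        referenced = {
            ontology
            for _, pair, ontology, _ in _iter_constraints(
                doc, TERM_FIELD_CONSTRAINTS)
            if pair.term_id
        }
        assert set(out.doc_info.ontology_versions) == referenced

    def test_augmented_from_prefers_doi(self, registries, valid_doc):
        out = augment_document(valid_doc, registries)
        assert out.doc_info.augmented_from == valid_doc.doc_info.doi
        valid_doc.doc_info.doi = None
        # doi is schema-required; force past validation to test precedence
        out = augment_document(valid_doc, registries, force=True)
        assert out.doc_info.augmented_from == \
            valid_doc.doc_info.version_id

    @pytest.mark.parametrize("seed", range(0, 30, 3))
    def test_idempotent(self, registries, seed):
        doc = make_valid_document(seed)
        once = augment_document(doc, registries)
        assert augment_document(once, registries) == once

    @pytest.mark.parametrize("seed", range(0, 30, 3))
    def test_non_destructive_tree_diff(self, registries, seed):
        doc = make_valid_document(seed)
        out = augment_document(doc, registries)
        before = _tree_items(doc.to_obj())
        after = _tree_items(out.to_obj())
        # every submitted leaf survives unchanged, except augmentation-
        # owned slots; nothing else is added
        assert {i for i in before if not _owned(i[0])} <= after
        added = {path for path, _ in after} - {path for path, _ in before}
        assert all(_owned(path) for path in added)

    def test_existing_summary_not_overwritten(self, registries, valid_doc):
        valid_doc.samples[0].sample_type.summary = "curated by hand"
        out = augment_document(valid_doc, registries)
        assert out.samples[0].sample_type.summary == "curated by hand"
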