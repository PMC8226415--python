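"""Deterministic generator of the artifact's entire test input supply:
registries, ontology snapshots, valid documents, rule-isolated invalid
documents and track-hub file sets.

All fixture ontology IRIs use the reserved ``TESTA``/``TESTS``/``TESTD``
prefixes so they can never collide with real ontologies.  All randomness
flows from a single integer seed.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

from . import schema as sch
from .model import (
    Checksum,
    ContactInfo,
    DocInfo,
    Experiment,
    FairDocument,
    Sample,
    SampleType,
    Study,
    Target,
    TermPair,
    Track,
    TrackCollection,
)
from .registries import (
    AssemblyEntry,
    CurieEntry,
    OntologySnapshot,
    OntologyTerm,
    RegistrySet,
)

# ---------------------------------------------------------------------------
# registry fixtures
# ---------------------------------------------------------------------------

_ASSAY_TERMS = [
    # (iri, label, parents)
    ("TESTA:0000001", "experimental procedure", ()),
    (sch.ASSAY_CLASS, "assay", ("TESTA:0000001",)),
    (sch.GENE_TARGETED_CLASS, "gene-targeted assay", (sch.ASSAY_CLASS,)),
    (sch.FEATURE_TARGETED_CLASS, "feature-targeted assay", (sch.ASSAY_CLASS,)),
    (sch.PHENOTYPE_TARGETED_CLASS, "phenotype-targeted assay",
     (sch.ASSAY_CLASS,)),
    (sch.UNTARGETED_CLASS, "untargeted assay", (sch.ASSAY_CLASS,)),
    ("TESTA:0000021", "ChIP-seq assay", (sch.GENE_TARGETED_CLASS,)),
    ("TESTA:0000022", "CUT&RUN assay", (sch.GENE_TARGETED_CLASS,)),
    ("TESTA:0000023", "DNase-seq assay", (sch.FEATURE_TARGETED_CLASS,)),
    ("TESTA:0000024", "ATAC-seq assay", (sch.FEATURE_TARGETED_CLASS,)),
    ("TESTA:0000025", "GWAS assay", (sch.PHENOTYPE_TARGETED_CLASS,)),
    ("TESTA:0000026", "RNA-seq assay", (sch.UNTARGETED_CLASS,)),
    ("TESTA:0000027", "whole-genome bisulfite sequencing assay",
     (sch.UNTARGETED_CLASS,)),
    (sch.DATA_FORMAT_CLASS, "data format", ("TESTA:0000001",)),
    ("TESTA:0000031", "bigWig", (sch.DATA_FORMAT_CLASS,)),
    ("TESTA:0000032", "bigBed", (sch.DATA_FORMAT_CLASS,)),
    ("TESTA:0000033", "BED", (sch.DATA_FORMAT_CLASS,)),
    ("TESTA:0000034", "VCF", (sch.DATA_FORMAT_CLASS,)),
    ("TESTA:0000035", "bedGraph", (sch.DATA_FORMAT_CLASS,)),
    ("TESTA:0000040", "biological target", ("TESTA:0000001",)),
    (sch.GENE_PRODUCT_CLASS, "gene product", ("TESTA:0000040",)),
    ("TESTA:0000042", "protein", (sch.GENE_PRODUCT_CLASS,)),
    ("TESTA:0000043", "messenger RNA", (sch.GENE_PRODUCT_CLASS,)),
    (sch.MACROMOL_STRUCTURE_CLASS, "macromolecular structure",
     ("TESTA:0000040",)),
    ("TESTA:0000045", "chromatin loop", (sch.MACROMOL_STRUCTURE_CLASS,)),
    ("TESTA:0000046", "nucleosome", (sch.MACROMOL_STRUCTURE_CLASS,)),
    (sch.SEQUENCE_FEATURE_CLASS, "sequence feature", ("TESTA:0000040",)),
    ("TESTA:0000048", "transcription factor binding site",
     (sch.SEQUENCE_FEATURE_CLASS,)),
    ("TESTA:0000049", "open chromatin region",
     (sch.SEQUENCE_FEATURE_CLASS,)),
]

_SAMPLE_TERMS = [
    ("TESTS:0000001", "biological entity", ()),
    ("TESTS:0000010", "biospecimen", ("TESTS:0000001",)),
    (sch.CELL_LINE_CLASS, "cell line", ("TESTS:0000010",)),
    (sch.CELL_TYPE_CLASS, "cell type", ("TESTS:0000010",)),
    (sch.ABNORMAL_CELL_TYPE_CLASS, "abnormal cell type",
     ("TESTS:0000010",)),
    (sch.ORGANISM_PART_CLASS, "organism part", ("TESTS:0000010",)),
    ("TESTS:0000021", "H1-hESC", (sch.CELL_LINE_CLASS,)),
    ("TESTS:0000022", "K562", (sch.CELL_LINE_CLASS,)),
    ("TESTS:0000023", "GM12878", (sch.CELL_LINE_CLASS,)),
    ("TESTS:0000031", "B cell, CD19 positive", (sch.CELL_TYPE_CLASS,)),
    ("TESTS:0000032", "T cell", (sch.CELL_TYPE_CLASS,)),
    ("TESTS:0000033", "monocyte", (sch.CELL_TYPE_CLASS,)),
    ("TESTS:0000041", "chronic lymphocytic leukemia cell",
     (sch.ABNORMAL_CELL_TYPE_CLASS,)),
    ("TESTS:0000042", "acute myeloid leukemia cell",
     (sch.ABNORMAL_CELL_TYPE_CLASS,)),
    ("TESTS:0000051", "liver", (sch.ORGANISM_PART_CLASS,)),
    ("TESTS:0000052", "brain", (sch.ORGANISM_PART_CLASS,)),
    ("TESTS:0000053", "venous blood", (sch.ORGANISM_PART_CLASS,)),
    (sch.PHENOTYPE_CLASS, "phenotype", ("TESTS:0000001",)),
    ("TESTS:0000061", "multiple sclerosis", (sch.PHENOTYPE_CLASS,)),
    ("TESTS:0000062", "rheumatoid arthritis", (sch.PHENOTYPE_CLASS,)),
    ("TESTS:0000063", "healthy", (sch.PHENOTYPE_CLASS,)),
]

_DATA_USE_TERMS = [
    (sch.DATA_USE_ROOT, "data use condition", ()),
    ("TESTD:0000010", "open access", (sch.DATA_USE_ROOT,)),
    ("TESTD:0000011", "general research use", ("TESTD:0000010",)),
    ("TESTD:0000012", "no restriction", ("TESTD:0000010",)),
    ("TESTD:0000020", "controlled access", (sch.DATA_USE_ROOT,)),
    ("TESTD:0000021", "disease-specific research", ("TESTD:0000020",)),
    ("TESTD:0000022", "multiple sclerosis research", ("TESTD:0000021",)),
    ("TESTD:0000023", "cancer research", ("TESTD:0000021",)),
    ("TESTD:0000024", "no commercial use", ("TESTD:0000020",)),
    ("TESTD:0000025", "publication moratorium", ("TESTD:0000020",)),
    ("TESTD:0000026", "ethics approval required", ("TESTD:0000020",)),
    ("TESTD:0000027", "collaboration required", ("TESTD:0000020",)),
    ("TESTD:0000028", "genetic studies only", ("TESTD:0000020",)),
]

_CURIE_ROWS = [
    ("insdc.gca", r"^GC[AF]_\d{9}\.\d+$",
     "https://example.org/asm/{accession}"),
    ("taxonomy", r"^\d+$", "https://example.org/taxonomy/{accession}"),
    ("pubmed", r"^\d+$", "https://example.org/pubmed/{accession}"),
    ("biosample", r"^SAM[NED][A-Z]?\d+$",
     "https://example.org/biosample/{accession}"),
    ("hgnc", r"^\d+$", "https://example.org/hgnc/{accession}"),
    ("geo", r"^GS[EM]\d+$", "https://example.org/geo/{accession}"),
    ("ega.experiment", r"^EGAX\d{11}$",
     "https://example.org/ega/{accession}"),
]

_ASSEMBLY_ROWS = [
    ("GRCh37", (("hg19", "ucsc"),), "insdc.gca:GCF_000001405.13"),
    ("GRCh38", (("hg38", "ucsc"),), "insdc.gca:GCF_000001405.26"),
    ("GRCm38", (("mm10", "ucsc"),), "insdc.gca:GCF_000001635.20"),
    ("GRCm39", (("mm39", "ucsc"),), "insdc.gca:GCF_000001635.27"),
]

#: (technique iri, recipe class) leaf pool for the generator
_TECHNIQUES = {
    "gene": ("TESTA:0000021", "TESTA:0000022"),
    "sequence_feature": ("TESTA:0000023", "TESTA:0000024"),
    "phenotype": ("TESTA:0000025",),
    "none": ("TESTA:0000026", "TESTA:0000027"),
}

_GENES = (
    ("hgnc:13723", "CTCF"),
    ("hgnc:4171", "GATA1"),
    ("hgnc:11998", "TP53"),
    ("hgnc:6204", "SPI1"),
)

_SEQUENCE_FEATURES = ("TESTA:0000048", "TESTA:0000049")
_PHENOTYPES = ("TESTS:0000061", "TESTS:0000062", "TESTS:0000063")
_FILE_FORMATS = ("TESTA:0000031", "TESTA:0000032", "TESTA:0000033",
                 "TESTA:0000034", "TESTA:0000035")
_DATA_USE_LEAVES = ("TESTD:0000011", "TESTD:0000012", "TESTD:0000022",
                    "TESTD:0000023", "TESTD:0000024", "TESTD:0000025",
                    "TESTD:0000026", "TESTD:0000027", "TESTD:0000028")

_BIOSPECIMEN_LEAVES = {
    sch.CELL_LINE_CLASS: ("TESTS:0000021", "TESTS:0000022", "TESTS:0000023"),
    sch.CELL_TYPE_CLASS: ("TESTS:0000031", "TESTS:0000032", "TESTS:0000033"),
    sch.ABNORMAL_CELL_TYPE_CLASS: ("TESTS:0000041", "TESTS:0000042"),
    sch.ORGANISM_PART_CLASS: ("TESTS:0000051", "TESTS:0000052",
                              "TESTS:0000053"),
}


def make_fixture_registries() -> RegistrySet:
    """The packaged offline registry bundle, built deterministically."""
    ontologies = {}
    for name, version, rows in (
        (sch.ASSAY_ONTOLOGY, "2021-03-01", _ASSAY_TERMS),
        (sch.SAMPLE_ONTOLOGY, "2020-11-15", _SAMPLE_TERMS),
        (sch.DATA_USE_ONTOLOGY, "1.0.2", _DATA_USE_TERMS),
    ):
        terms = [OntologyTerm(iri, label, parents)
                 for iri, label, parents in rows]
        ontologies[name] = OntologySnapshot(name, version, terms)
    return RegistrySet(
        curies={p: CurieEntry(p, pat, tpl) for p, pat, tpl in _CURIE_ROWS},
        assemblies=[AssemblyEntry(c, s, a) for c, s, a in _ASSEMBLY_ROWS],
        ontologies=ontologies,
    )


# ---------------------------------------------------------------------------
# document generator
# ---------------------------------------------------------------------------

def _maybe_extra(rng: random.Random, obj) -> None:
    if rng.random() < 0.10:
        obj.extra["my_lab_notes"] = f"note {rng.randint(1000, 9999)}"


def make_valid_document(seed: int, n_collections: int = 1,
                        n_studies: int = 2, n_samples: int = 3,
                        n_experiments: int = 4, n_tracks: int = 5
                        ) -> FairDocument:
    """A deterministic document satisfying every validation rule.

    All required attributes are populated, the reference graph is
    connected, roughly 20% of experiments are *in silico* aggregations
    (with a guaranteed chain of length >= 2 when ``n_experiments >= 3``),
    and roughly 10% of objects carry unknown extra fields.
    """
    if min(n_collections, n_studies, n_samples, n_experiments,
           n_tracks) < 1:
        raise ValueError("all object counts must be >= 1")
    rng = random.Random(seed)

    doc_info = DocInfo(
        local_id=f"doc_{seed}",
        version_id="1.0.0",
        version_date="2021-04-01",
        ontology_versions={},
        source_url=f"https://example.org/source/{seed}",
        doi=f"10.9999/test.{seed}",
    )

    collections = []
    for i in range(n_collections):
        coll = TrackCollection(
            local_id=f"coll_{i:03d}",
            name=f"Track collection {i}",
            description=f"Synthetic collection {i} for seed {seed}",
            source_url=f"https://example.org/coll/{seed}/{i}",
            contact=ContactInfo(name=f"Curator {i}",
                                email=f"curator{i}@example.org"),
        )
        _maybe_extra(rng, coll)
        collections.append(coll)

    studies = []
    for i in range(n_studies):
        study = Study(
            local_id=f"stud_{i:03d}",
            collection_ref=collections[i % n_collections].local_id,
            name=f"Study {i}",
            publications=[f"pubmed:{rng.randint(10000, 99999999)}"],
            contact=ContactInfo(name=f"PI {i}",
                                email=f"pi{i}@example.org"),
        )
        _maybe_extra(rng, study)
        studies.append(study)

    samples = []
    for i in range(n_samples):
        class_iri = rng.choice(sorted(_BIOSPECIMEN_LEAVES))
        _, child_name = sch.BIOSPECIMEN_CLASSES[class_iri]
        child_iri = rng.choice(_BIOSPECIMEN_LEAVES[class_iri])
        sample_type = SampleType()
        setattr(sample_type, child_name, TermPair(term_id=child_iri))
        sample = Sample(
            local_id=f"samp_{i:03d}",
            species="taxonomy:9606",
            biospecimen_class=TermPair(term_id=class_iri),
            sample_type=sample_type,
            phenotype=(TermPair(term_id=rng.choice(_PHENOTYPES))
                       if rng.random() < 0.3 else None),
            external_refs=[f"biosample:SAMN{rng.randint(0, 9999999):07d}"],
        )
        _maybe_extra(rng, sample)
        samples.append(sample)

    experiments = []
    agg_indices: set[int] = set()
    if n_experiments >= 3:
        agg_indices.update({n_experiments - 1, n_experiments - 2})
        for i in range(1, n_experiments - 2):
            if rng.random() < 0.10:
                agg_indices.add(i)
    for i in range(n_experiments):
        recipe = rng.choice(("gene", "gene", "sequence_feature",
                             "phenotype", "none"))
        technique = TermPair(term_id=rng.choice(_TECHNIQUES[recipe]))
        target = Target()
        if recipe == "gene":
            curie, symbol = rng.choice(_GENES)
            target.gene_id = TermPair(term_id=curie, term_label=symbol)
            if rng.random() < 0.3:
                target.target_details = "phosphorylated"
        elif recipe == "sequence_feature":
            target.sequence_feature = TermPair(
                term_id=rng.choice(_SEQUENCE_FEATURES))
        elif recipe == "phenotype":
            target.phenotype = TermPair(term_id=rng.choice(_PHENOTYPES))
        exp = Experiment(
            local_id=f"expt_{i:03d}",
            study_ref=studies[i % n_studies].local_id,
            technique=technique,
            target=target,
            lab_protocol_description=f"https://example.org/prot/lab/{i}",
            compute_protocol_description=(
                f"https://example.org/prot/compute/{i}"),
        )
        if i in agg_indices:
            # aggregate the immediately preceding experiment, which chains
            # the two guaranteed trailing aggregation nodes
            upstream = {i - 1}
            if i > 1 and rng.random() < 0.5:
                upstream.add(rng.randrange(0, i - 1))
            exp.aggregated_from = [experiments[j].local_id
                                   for j in sorted(upstream)]
        else:
            exp.sample_ref = samples[i % n_samples].local_id
        _maybe_extra(rng, exp)
        experiments.append(exp)

    tracks = []
    for i in range(n_tracks):
        canonical, synonyms, curie = _ASSEMBLY_ROWS[
            rng.randrange(len(_ASSEMBLY_ROWS))]
        annotation = rng.choice([canonical, synonyms[0][0]])
        file_url = f"https://example.org/files/{seed}/track_{i:03d}.bigwig"
        track = Track(
            local_id=f"trck_{i:03d}",
            source_coll_ref=collections[i % n_collections].local_id,
            experiment_ref=experiments[i % n_experiments].local_id,
            file_url=file_url,
            label_short=f"trk{i}",
            label_long=f"Synthetic track {i} (seed {seed})",
            description=f"Deterministic test track {i}",
            assembly_id=curie,
            annotation_name=annotation,
            raw_file_ids=[f"geo:GSM{rng.randint(1, 999999)}"],
            file_format=TermPair(term_id=rng.choice(_FILE_FORMATS)),
            type_of_condensed_data=rng.choice(sch.CONDENSED_DATA_VOCAB),
            genomic_track_type=rng.choice(sch.TRACK_TYPE_VOCAB),
            checksum=Checksum(
                method="md5",
                value=hashlib.md5(file_url.encode()).hexdigest(),
            ),
        )
        if rng.random() < 0.6:
            n_terms = rng.randint(1, 2)
            track.data_use_conditions = [
                TermPair(term_id=iri)
                for iri in rng.sample(_DATA_USE_LEAVES, n_terms)
            ]
            track.data_use_url = f"https://example.org/policy/{seed}/{i}"
        _maybe_extra(rng, track)
        tracks.append(track)

    return FairDocument(doc_info=doc_info, collections=collections,
                        studies=studies, samples=samples,
                        experiments=experiments, tracks=tracks)


# ---------------------------------------------------------------------------
# rule-isolated invalid documents
# ---------------------------------------------------------------------------

INJECTABLE_KINDS = (
    "schema",
    "unique_violation",
    "foreign_ref",
    "curie_syntax",
    "curie_prefix",
    "curie_accession",
    "ontology_term",
    "ontology_ancestor",
    "ontology_label_mismatch",
    "assembly_name",
    "checksum_format",
    "doi_format",
    "cardinality",
    "aggregation_cycle",
    "biospecimen_child_missing",
)


def _first_sampled_experiment(doc: FairDocument) -> Experiment:
    for exp in doc.experiments:
        if exp.sample_ref:
            return exp
    raise AssertionError("generator always emits sampled experiments")


def make_invalid_document(seed: int, rule_kind: str,
                          **counts) -> FairDocument:
    """A generated document with exactly one minimal violation of
    ``rule_kind`` injected (and nothing else broken)."""
    if rule_kind not in INJECTABLE_KINDS:
        raise ValueError(f"unsupported rule kind {rule_kind!r}")
    counts.setdefault("n_samples", 3)
    doc = make_valid_document(seed, **counts)

    if rule_kind == "schema":
        doc.collections[0].name = None
    elif rule_kind == "unique_violation":
        # append a full copy so existing references stay resolvable
        import copy as _copy

        doc.samples.append(_copy.deepcopy(doc.samples[0]))
    elif rule_kind == "foreign_ref":
        _first_sampled_experiment(doc).sample_ref = "samp_missing"
    elif rule_kind == "curie_syntax":
        doc.studies[0].publications[0] = "nocolon"
    elif rule_kind == "curie_prefix":
        doc.studies[0].publications[0] = "unregistered:12345"
    elif rule_kind == "curie_accession":
        doc.studies[0].publications[0] = "pubmed:notdigits"
    elif rule_kind == "ontology_term":
        doc.experiments[0].technique = TermPair(term_id="TESTA:9999999")
    elif rule_kind == "ontology_ancestor":
        # exists in the assay snapshot but outside the assay subtree
        doc.experiments[0].technique = TermPair(term_id="TESTA:0000031")
    elif rule_kind == "ontology_label_mismatch":
        doc.experiments[0].technique.term_label = "definitely wrong label"
    elif rule_kind == "assembly_name":
        track = doc.tracks[0]
        track.assembly_id = "insdc.gca:GCF_000001405.13"  # GRCh37
        track.annotation_name = "hg38"
    elif rule_kind == "checksum_format":
        doc.tracks[0].checksum.value = "abc123"
    elif rule_kind == "doi_format":
        doc.doc_info.doi = "11.9999/not-a-doi"
    elif rule_kind == "cardinality":
        # neither a sample nor an upstream experiment
        exp = _first_sampled_experiment(doc)
        exp.sample_ref = None
        exp.aggregated_from = None
    elif rule_kind == "aggregation_cycle":
        exp = _first_sampled_experiment(doc)
        exp.sample_ref = None
        exp.aggregated_from = [exp.local_id]
    elif rule_kind == "biospecimen_child_missing":
        sample = doc.samples[0]
        _, child = sch.BIOSPECIMEN_CLASSES[sample.biospecimen_class.term_id]
        setattr(sample.sample_type, child, None)
    return doc


# ---------------------------------------------------------------------------
# track-hub fixtures
# ---------------------------------------------------------------------------

@dataclass
class HubFixture:
    """A deterministic UCSC-layout track-hub file set."""

    hub_text: str
    genomes_text: str
    trackdb_texts: dict = field(default_factory=dict)
    #: number of leaf stanzas carrying a data URL, counted at build time
    n_data_stanzas: int = 0


def make_hub_fixture(seed: int) -> HubFixture:
    """Generate hub.txt / genomes.txt / per-genome trackDb.txt contents.

    Each trackDb mixes container stanzas (no data URL), leaf stanzas with
    ``bigDataUrl`` (some carrying a free-form ``metadata`` line) and the
    occasional leaf without a data URL.
    """
    rng = random.Random(seed)
    genomes = rng.sample(["hg19", "hg38", "mm10"], rng.randint(1, 2))

    hub_text = "\n".join([
        f"hub testhub{seed}",
        f"shortLabel Test hub {seed}",
        f"longLabel Synthetic track hub fixture number {seed}",
        "genomesFile genomes.txt",
        f"email hub{seed}@example.org",
    ]) + "\n"

    genome_blocks = [
        f"genome {g}\ntrackDb {g}/trackDb.txt" for g in genomes
    ]
    genomes_text = "\n\n".join(genome_blocks) + "\n"

    trackdbs = {}
    n_data = 0
    for genome in genomes:
        stanzas = []
        container = f"comp_{genome}"
        stanzas.append("\n".join([
            f"track {container}",
            "compositeTrack on",
            f"shortLabel Composite {genome}",
            f"longLabel Composite container for {genome}",
            "type bigWig",
        ]))
        for i in range(rng.randint(2, 5)):
            name = f"trk_{genome}_{i}"
            fmt = rng.choice(["bigWig 0 100", "bigBed 6 +"])
            ext = "bw" if fmt.startswith("bigWig") else "bb"
            lines = [
                f"track {name}",
                f"shortLabel {genome} track {i}",
                f"longLabel Synthetic {genome} data track {i} "
                f"(seed {seed})",
                f"type {fmt}",
                f"bigDataUrl https://example.org/hub{seed}/{genome}/"
                f"{name}.{ext}",
            ]
            if rng.random() < 0.5:
                lines.insert(1, f"parent {container} on")
            if rng.random() < 0.4:
                lines.append(
                    f'metadata assay_lab="Lab {rng.randint(1, 9)}" '
                    f"replicate={rng.randint(1, 3)}"
                )
            stanzas.append("\n".join(lines))
            n_data += 1
        if rng.random() < 0.3:
            stanzas.append("\n".join([
                f"track empty_{genome}",
                f"shortLabel Empty {genome}",
                f"longLabel A stanza without a data URL",
                "type bigWig",
            ]))
        trackdbs[genome] = "\n\n".join(stanzas) + "\n"

    return HubFixture(hub_text, genomes_text, trackdbs, n_data)
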