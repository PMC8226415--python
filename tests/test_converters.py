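import pytest

from trackmeta.augmenter import augment_document
from trackmeta.converters import (
    GSuiteTable,
    from_gsuite,
    import_trackhub,
    parse_gsuite,
    parse_stanzas,
    to_gsuite,
)
from trackmeta.errors import GSuiteFormatError, HubFormatError
from trackmeta.fixtures import (
    make_hub_fixture,
    make_valid_document,
)

MINIMAL_HUB = """\
hub minihub
shortLabel Mini hub
longLabel A minimal single-track hub
genomesFile genomes.txt
email mini@example.org
"""

MINIMAL_GENOMES = """\
genome hg19
trackDb hg19/trackDb.txt
"""

MINIMAL_TRACKDB = """\
track wig1
shortLabel Wiggle one
longLabel The only data track
type bigWig 0 30
bigDataUrl https://example.org/data/wig1.bw
"""


class TestToGSuite:
    def test_one_row_per_track_first_column_uri(self, valid_doc):
        table = to_gsuite(valid_doc)
        assert len(table.rows) == len(valid_doc.tracks) == 5
        assert table.columns[0] == "uri"
        assert table.rows[0][0] == valid_doc.tracks[0].file_url

    def test_zero_tracks_header_only(self):
        doc = make_valid_document(1, n_tracks=1)
        doc.tracks = []
        text = to_gsuite(doc).to_text()
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert lines == []
        assert any(l.startswith("###uri\t") for l in text.splitlines())

    def test_unaugmented_summary_columns_are_missing(self, valid_doc):
        table = to_gsuite(valid_doc)
        idx = {c: i for i, c in enumerate(table.columns)}
        # independent walk: columns derived from augmentation-owned fields
        # must all be "." before augmentation
        for row in table.rows:
            for col in ("file_format", "technique", "target_summary",
                        "sample_summary"):
                assert row[idx[col]] == "."

    def test_augmented_document_fills_summary_columns(self, registries):
        doc = augment_document(make_valid_document(8), registries)
        table = to_gsuite(doc)
        idx = {c: i for i, c in enumerate(table.columns)}
        assert any(row[idx["technique"]] != "." for row in table.rows)
        assert all(row[idx["file_format"]] != "." for row in table.rows)


class TestParseGSuite:
    def test_round_trip_through_text(self, valid_doc):
        table = to_gsuite(valid_doc)
        parsed = parse_gsuite(table.to_text())
        assert parsed.columns == table.columns
        assert parsed.rows == table.rows

    def test_ragged_row_names_line(self):
        text = "###uri\ttitle\nhttps://x\tok\nhttps://y\n"
        with pytest.raises(GSuiteFormatError, match="line 3"):
            parse_gsuite(text)

    def test_missing_header(self):
        with pytest.raises(GSuiteFormatError):
            parse_gsuite("# only a comment\n")

    def test_header_must_start_with_uri(self):
        with pytest.raises(GSuiteFormatError):
            parse_gsuite("###title\turi\nrow\trow\n")

    def test_duplicate_columns_rejected(self):
        with pytest.raises(GSuiteFormatError):
            GSuiteTable(columns=("uri", "uri"), rows=[])


class TestFromGSuite:
    @pytest.mark.parametrize("seed", range(0, 30, 3))
    def test_track_subset_round_trip(self, registries, seed):
        doc = augment_document(make_valid_document(seed), registries)
        back = from_gsuite(to_gsuite(doc).to_text())
        assert len(back.tracks) == len(doc.tracks)
        for orig, imported in zip(doc.tracks, back.tracks):
            assert imported.file_url == orig.file_url
            assert imported.label_short == orig.label_short
            assert imported.annotation_name == orig.annotation_name
            assert imported.genomic_track_type == orig.genomic_track_type

    def test_dot_cells_become_absent_fields(self):
        text = "###uri\ttitle\tgenome\nhttps://x/t.bw\t.\thg19\n"
        doc = from_gsuite(text)
        track = doc.tracks[0]
        assert track.label_short is None
        assert track.annotation_name == "hg19"

    def test_synthetic_collection_attached(self):
        doc = from_gsuite("###uri\nhttps://x/t.bw\n")
        assert len(doc.collections) == 1
        assert doc.tracks[0].source_coll_ref == \
            doc.collections[0].local_id


class TestStanzaParsing:
    def test_blank_line_separated_blocks(self):
        stanzas = parse_stanzas(MINIMAL_TRACKDB + "\n" + MINIMAL_TRACKDB
                                .replace("wig1", "wig2"))
        assert [s.name for s in stanzas] == ["wig1", "wig2"]
        assert stanzas[0].pairs["type"] == "bigWig 0 30"

    def test_indented_child_lines_flattened(self):
        text = ("track parentTrack\ncompositeTrack on\n"
                "shortLabel P\nlongLabel Parent\ntype bigWig\n\n"
                "    track child\n    parent parentTrack on\n"
                "    bigDataUrl https://x/c.bw\n    type bigWig\n")
        stanzas = parse_stanzas(text)
        assert stanzas[1].pairs["parent"] == "parentTrack on"

    def test_unkeyed_stanza_rejected(self):
        with pytest.raises(HubFormatError):
            parse_stanzas("shortLabel floating\nlongLabel No anchor key\n")


class TestImportTrackhub:
    def test_minimal_hub_one_collection_one_track(self, registries):
        doc, log = import_trackhub(
            MINIMAL_HUB, MINIMAL_GENOMES,
            {"hg19": MINIMAL_TRACKDB}, registries)
        assert len(doc.collections) == 1
        assert len(doc.tracks) == 1
        track = doc.tracks[0]
        assert track.file_url == "https://example.org/data/wig1.bw"
        assert track.label_short == "Wiggle one"
        assert track.label_long == "The only data track"
        assert track.annotation_name == "hg19"
        # recognized genome also yields the assembly accession
        assert track.assembly_id == "insdc.gca:GCF_000001405.13"
        assert doc.collections[0].contact.email == "mini@example.org"

    def test_container_without_data_url_skipped_and_logged(
            self, registries):
        trackdb = ("track parent1\nsuperTrack on\nshortLabel P\n"
                   "longLabel Parent container\ntype bigWig\n\n"
                   + MINIMAL_TRACKDB)
        doc, log = import_trackhub(MINIMAL_HUB, MINIMAL_GENOMES,
                                   {"hg19": trackdb}, registries)
        assert len(doc.tracks) == 1
        assert "skipped_stanza" in log.kinds()

    def test_metadata_pairs_retained_as_unknown_fields(self, registries):
        trackdb = MINIMAL_TRACKDB + \
            'metadata assay_lab="Lab 9" replicate=2\n'
        doc, _ = import_trackhub(MINIMAL_HUB, MINIMAL_GENOMES,
                                 {"hg19": trackdb}, registries)
        assert doc.tracks[0].extra == {"assay_lab": "Lab 9",
                                       "replicate": "2"}

    def test_unknown_genome_kept_verbatim_and_flagged(self, registries):
        genomes = MINIMAL_GENOMES.replace("hg19", "weirdAsm9")
        doc, log = import_trackhub(MINIMAL_HUB, genomes,
                                   {"weirdAsm9": MINIMAL_TRACKDB},
                                   registries)
        assert doc.tracks[0].annotation_name == "weirdAsm9"
        assert doc.tracks[0].assembly_id is None
        assert "unknown_genome" in log.kinds()

    def test_unmapped_type_kept_as_plain_label(self, registries):
        trackdb = MINIMAL_TRACKDB.replace("type bigWig 0 30",
                                          "type exoticFormat 1")
        doc, log = import_trackhub(MINIMAL_HUB, MINIMAL_GENOMES,
                                   {"hg19": trackdb}, registries)
        assert doc.tracks[0].file_format.term_label == "exoticFormat"
        assert doc.tracks[0].file_format.term_id is None

    def test_draft_fails_validation_with_only_schema_issues(
            self, validator, registries):
        doc, _ = import_trackhub(MINIMAL_HUB, MINIMAL_GENOMES,
                                 {"hg19": MINIMAL_TRACKDB}, registries)
        report = validator.validate(doc)
        assert not report.ok
        # independent scan of the report: every issue is a schema issue,
        # and all of them are about missing required fields
        assert {i.rule_kind for i in report.issues} == {"schema"}
        assert all("required" in i.message for i in report.issues)

    def test_hub_without_hub_stanza_rejected(self, registries):
        with pytest.raises(HubFormatError):
            import_trackhub("genome hg19\n", MINIMAL_GENOMES,
                            {"hg19": MINIMAL_TRACKDB}, registries)

    @pytest.mark.parametrize("seed", range(8))
    def test_import_conservation_on_generated_hubs(self, registries,
                                                   seed):
        fixture = make_hub_fixture(seed)
        doc, _ = import_trackhub(fixture.hub_text, fixture.genomes_text,
                                 fixture.trackdb_texts, registries)
        # independent stanza counter over the raw text
        expected = sum(
            block.count("bigDataUrl")
            for text in fixture.trackdb_texts.values()
            for block in text.split("\n\n")
            if "compositeTrack" not in block and "superTrack" not in block
        )
        assert len(doc.tracks) == expected == fixture.n_data_stanzas
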