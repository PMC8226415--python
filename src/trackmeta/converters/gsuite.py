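"""Tabular track-collection export (GSuite dialect) and its inverse.

Dialect, bit-exactly:

* any number of ``#``-prefixed comment lines (the preamble);
* one header line starting ``###`` followed by tab-separated column
  names, the first of which is ``uri``;
* one tab-separated row per track, with ``.`` for a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import GSuiteFormatError
from ..model import FairDocument, TermPair, Track, TrackCollection

MISSING = "."

#: fixed column layout of the export
COLUMNS = (
    "uri",
    "title",
    "genome",
    "file_format",
    "track_type",
    "condensed_data_type",
    "technique",
    "target_summary",
    "sample_summary",
    "study_name",
    "source_collection",
)


@dataclass
class GSuiteTable:
    preamble: list = field(default_factory=list)
    columns: tuple = COLUMNS
    rows: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.columns)) != len(self.columns):
            raise GSuiteFormatError("duplicate column names", 1)
        if not self.columns or self.columns[0] != "uri":
            raise GSuiteFormatError("first column must be 'uri'", 1)
        for row in self.rows:
            if len(row) != len(self.columns):
                raise GSuiteFormatError(
                    f"row has {len(row)} fields, expected "
                    f"{len(self.columns)}", 0)

    def to_text(self) -> str:
        lines = list(self.preamble)
        lines.append("###" + "\t".join(self.columns))
        lines += ["\t".join(row) for row in self.rows]
        return "\n".join(lines) + "\n"


def _cell(value) -> str:
    if value is None or value == "":
        return MISSING
    # tabs and newlines are structural in this dialect
    return str(value).replace("\t", " ").replace("\n", " ")


def to_gsuite(doc: FairDocument) -> GSuiteTable:
    """One row per track; summary/label columns fall back to ``.`` on
    unaugmented documents."""
    collections = {c.local_id: c for c in doc.collections}
    studies = {s.local_id: s for s in doc.studies}
    samples = {s.local_id: s for s in doc.samples}
    experiments = {e.local_id: e for e in doc.experiments}

    rows = []
    for track in doc.tracks:
        exp = experiments.get(track.experiment_ref)
        study = studies.get(exp.study_ref) if exp else None
        sample = samples.get(exp.sample_ref) if exp else None
        coll = collections.get(track.source_coll_ref)
        technique = exp.technique.term_label \
            if exp and exp.technique else None
        target_summary = exp.target.summary if exp and exp.target else None
        sample_summary = sample.sample_type.summary \
            if sample and sample.sample_type else None
        rows.append([
            _cell(track.file_url),
            _cell(track.label_short),
            _cell(track.annotation_name),
            _cell(track.file_format.term_label if track.file_format
                  else None),
            _cell(track.genomic_track_type),
            _cell(track.type_of_condensed_data),
            _cell(technique),
            _cell(target_summary),
            _cell(sample_summary),
            _cell(study.name if study else None),
            _cell(coll.name if coll else None),
        ])
    preamble = ["# genomic track collection export"]
    return GSuiteTable(preamble=preamble, columns=COLUMNS, rows=rows)


def parse_gsuite(text: str) -> GSuiteTable:
    """Parse the dialect back into a table; errors carry line numbers."""
    preamble: list[str] = []
    columns: tuple | None = None
    rows: list[list[str]] = []
    header_line = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if columns is None:
            if line.startswith("###"):
                columns = tuple(line[3:].split("\t"))
                header_line = lineno
                if not columns or columns[0] != "uri":
                    raise GSuiteFormatError(
                        "first header column must be 'uri'", lineno)
            elif line.startswith("#") or not line.strip():
                preamble.append(line)
            else:
                raise GSuiteFormatError(
                    "data line before '###' header", lineno)
            continue
        if not line.strip():
            continue
        row = line.split("\t")
        if len(row) != len(columns):
            raise GSuiteFormatError(
                f"row has {len(row)} fields, expected {len(columns)}",
                lineno)
        rows.append(row)
    if columns is None:
        raise GSuiteFormatError("missing '###' header line",
                                header_line or 1)
    return GSuiteTable(preamble=preamble, columns=columns, rows=rows)


def from_gsuite(text: str) -> FairDocument:
    """Reconstruct a partial document: one Track per row plus a single
    synthetic collection; ``.`` cells become absent fields."""
    table = parse_gsuite(text)
    col_idx = {name: i for i, name in enumerate(table.columns)}

    def get(row, name):
        idx = col_idx.get(name)
        if idx is None:
            return None
        value = row[idx]
        return None if value == MISSING else value

    collection = TrackCollection(local_id="gsuite_import",
                                 name="Imported track collection")
    tracks = []
    for i, row in enumerate(table.rows):
        fmt = get(row, "file_format")
        tracks.append(Track(
            local_id=f"trck_{i:03d}",
            source_coll_ref=collection.local_id,
            file_url=get(row, "uri"),
            label_short=get(row, "title"),
            annotation_name=get(row, "genome"),
            file_format=(TermPair(term_label=fmt)
                         if fmt is not None else None),
            genomic_track_type=get(row, "track_type"),
            type_of_condensed_data=get(row, "condensed_data_type"),
        ))
    return FairDocument(collections=[collection], tracks=tracks)
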