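"""Track-hub text import: hub.txt / genomes.txt / trackDb.txt stanzas.

Stanzas are blank-line-separated blocks of key/value metadata lines; the
key is the first whitespace-delimited token.  Child-track indentation is
flattened and only leaf stanzas carrying a ``bigDataUrl`` become tracks.
The full UCSC settings grammar is out of scope; everything unmapped is
either retained as unknown fields (``metadata`` pairs) or noted in the
import log.  The result is a draft expected to FAIL validation until
curated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ..errors import HubFormatError, UnknownAssemblyError
from ..model import (
    ContactInfo,
    DocInfo,
    FairDocument,
    TermPair,
    Track,
    TrackCollection,
)
from ..registries import RegistrySet, assembly_entry_for, default_registries

#: trackDb "type" first token -> fixture file-format term IRI
TYPE_TO_FORMAT_IRI = {
    "bigWig": "TESTA:0000031",
    "bigBed": "TESTA:0000032",
    "bed": "TESTA:0000033",
    "vcfTabix": "TESTA:0000034",
    "bedGraph": "TESTA:0000035",
}

_METADATA_PAIR_RE = re.compile(r'(\S+?)=("[^"]*"|\S+)')


@dataclass
class HubStanza:
    """One key/value block from a hub file."""

    kind: str  # "hub", "genome" or "track"
    pairs: dict = field(default_factory=dict)

    @property
    def name(self) -> str | None:
        return self.pairs.get(self.kind)


@dataclass
class ImportLog:
    """Curation notes produced while importing: skipped stanzas, fields
    that could not be mapped, unrecognized genome names."""

    entries: list = field(default_factory=list)

    def add(self, kind: str, message: str) -> None:
        self.entries.append((kind, message))

    def kinds(self) -> set:
        return {kind for kind, _ in self.entries}


def parse_stanzas(text: str) -> list[HubStanza]:
    """Split a hub file into stanzas (leading indentation flattened)."""
    stanzas: list[HubStanza] = []
    block: dict[str, str] = {}

    def flush():
        nonlocal block
        if block:
            for kind in ("track", "genome", "hub"):
                if kind in block:
                    stanzas.append(HubStanza(kind, block))
                    break
            else:
                raise HubFormatError(
                    f"stanza without a hub/genome/track key: "
                    f"{sorted(block)!r}"
                )
            block = {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            continue
        key, _, value = line.partition(" ")
        if not key:
            raise HubFormatError(f"unparseable line: {raw!r}")
        block[key] = value.strip()
    flush()
    return stanzas


def _parse_metadata_pairs(value: str) -> dict:
    return {
        key: val.strip('"')
        for key, val in _METADATA_PAIR_RE.findall(value)
    }


def import_trackhub(hub_text: str, genomes_text: str,
                    trackdb_texts: dict,
                    registries: RegistrySet | None = None
                    ) -> tuple[FairDocument, ImportLog]:
    """Map a track-hub file set onto a draft document.

    ``trackdb_texts`` maps genome name -> trackDb.txt content.  Returns
    the draft plus an :class:`ImportLog` enumerating everything that
    needs curation.
    """
    registries = registries or default_registries()
    log = ImportLog()

    hub_stanzas = [s for s in parse_stanzas(hub_text) if s.kind == "hub"]
    if not hub_stanzas:
        raise HubFormatError("hub.txt contains no 'hub' stanza")
    hub = hub_stanzas[0]

    collection = TrackCollection(
        local_id=hub.name or "hub",
        name=hub.pairs.get("shortLabel"),
        description=hub.pairs.get("longLabel"),
        contact=(ContactInfo(email=hub.pairs["email"])
                 if "email" in hub.pairs else None),
    )
    for missing in ("shortLabel", "longLabel", "email"):
        if missing not in hub.pairs:
            log.add("missing_field", f"hub.txt lacks {missing!r}")
    log.add("missing_field",
            "collection source_url cannot be derived from a hub")

    genome_stanzas = [s for s in parse_stanzas(genomes_text)
                      if s.kind == "genome"]
    if not genome_stanzas:
        raise HubFormatError("genomes.txt contains no 'genome' stanza")

    tracks: list[Track] = []
    seen_ids: set[str] = set()
    for genome_stanza in genome_stanzas:
        genome = genome_stanza.name
        if genome not in trackdb_texts:
            log.add("skipped_stanza",
                    f"no trackDb content supplied for genome {genome!r}")
            continue
        assembly_id = None
        try:
            entry = assembly_entry_for(genome, registries)
            assembly_id = entry.assembly_curie
        except UnknownAssemblyError:
            log.add("unknown_genome",
                    f"genome {genome!r} is not a registered assembly "
                    f"name; kept verbatim")

        stanzas = [s for s in parse_stanzas(trackdb_texts[genome])
                   if s.kind == "track"]
        parents = {s.pairs["parent"].split()[0]
                   for s in stanzas if "parent" in s.pairs}
        for stanza in stanzas:
            name = stanza.name
            is_container = (
                name in parents
                or "compositeTrack" in stanza.pairs
                or "superTrack" in stanza.pairs
                or "container" in stanza.pairs
            )
            if is_container or "bigDataUrl" not in stanza.pairs:
                log.add("skipped_stanza",
                        f"stanza {name!r} ({genome}): container or no "
                        f"bigDataUrl; no track emitted")
                continue
            local_id = name
            while local_id in seen_ids:
                local_id += "_dup"
            seen_ids.add(local_id)

            type_token = stanza.pairs.get("type", "").split(" ")[0]
            file_format = None
            if type_token:
                iri = TYPE_TO_FORMAT_IRI.get(type_token)
                if iri is None:
                    log.add("missing_field",
                            f"stanza {name!r}: type {type_token!r} has no "
                            f"file-format mapping; kept as plain label")
                    file_format = TermPair(term_label=type_token)
                else:
                    file_format = TermPair(term_id=iri)

            track = Track(
                local_id=local_id,
                source_coll_ref=collection.local_id,
                file_url=stanza.pairs["bigDataUrl"],
                label_short=stanza.pairs.get("shortLabel"),
                label_long=stanza.pairs.get("longLabel"),
                description=stanza.pairs.get("longLabel"),
                annotation_name=genome,
                assembly_id=assembly_id,
                file_format=file_format,
            )
            if "metadata" in stanza.pairs:
                for key, value in _parse_metadata_pairs(
                    stanza.pairs["metadata"]
                ).items():
                    track.extra.setdefault(key, value)
            for missing in ("shortLabel", "longLabel"):
                if missing not in stanza.pairs:
                    log.add("missing_field",
                            f"stanza {name!r} lacks {missing!r}")
            log.add("missing_field",
                    f"track {local_id!r}: experiment_ref, raw_file_ids, "
                    f"vocabulary fields and checksum need curation")
            tracks.append(track)

    doc = FairDocument(
        doc_info=DocInfo(local_id=collection.local_id),
        collections=[collection],
        tracks=tracks,
    )
    return doc, log
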