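"""Offline stand-ins for identifier and ontology services.

Live services (prefix resolution, assembly naming, ontology lookup) are an
online concern; validation only needs their syntax and registry semantics.
Everything here is backed by small TSV tables that can be swapped for real
registry exports via ``load_registry_dir``.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    ConfigurationError,
    CurieAccessionError,
    CuriePrefixError,
    CurieSyntaxError,
    OntologyCycleError,
    OntologyTermError,
    UnknownAssemblyError,
)

#: DOI syntax after normalization: "10.<registrant>/<suffix>".
_DOI_RE = re.compile(r"^10\.\d+/\S+$")

NAMING_SCHEMES = ("grc", "ucsc")


@dataclass(frozen=True)
class CurieEntry:
    """One prefix row of the compact-identifier registry."""

    prefix: str
    accession_pattern: str
    url_template: str

    def __post_init__(self):
        if ":" in self.prefix or self.prefix != self.prefix.lower():
            raise ConfigurationError(f"bad CURIE prefix {self.prefix!r}")
        re.compile(self.accession_pattern)  # must compile


@dataclass(frozen=True)
class AssemblyEntry:
    """A canonical assembly name, its registered synonyms and its accession."""

    canonical_name: str
    synonyms: tuple[tuple[str, str], ...]  # (synonym, naming_scheme)
    assembly_curie: str

    def __post_init__(self):
        for syn, scheme in self.synonyms:
            if syn == self.canonical_name:
                raise ConfigurationError(
                    f"canonical name {syn!r} listed among its own synonyms"
                )
            if scheme not in NAMING_SCHEMES:
                raise ConfigurationError(f"unknown naming scheme {scheme!r}")


@dataclass(frozen=True)
class OntologyTerm:
    iri: str
    label: str
    parent_iris: tuple[str, ...] = ()


class OntologySnapshot:
    """A versioned, frozen view of one ontology: labelled terms in a DAG."""

    def __init__(self, name: str, version: str, terms: list[OntologyTerm]):
        self.name = name
        self.version = version
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.iri in self.terms:
                raise ConfigurationError(f"duplicate term iri {term.iri!r}")
            self.terms[term.iri] = term
        for term in self.terms.values():
            for parent in term.parent_iris:
                if parent not in self.terms:
                    raise ConfigurationError(
                        f"{term.iri}: parent {parent!r} not in snapshot"
                    )
        self._reject_cycles()

    def _reject_cycles(self):
        # Kahn's algorithm over child->parent edges; leftovers are cyclic.
        indeg = {iri: 0 for iri in self.terms}
        for term in self.terms.values():
            for parent in term.parent_iris:
                indeg[parent] += 1
        queue = deque(iri for iri, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            iri = queue.popleft()
            seen += 1
            for parent in self.terms[iri].parent_iris:
                indeg[parent] -= 1
                if indeg[parent] == 0:
                    queue.append(parent)
        if seen != len(self.terms):
            raise OntologyCycleError(
                f"ontology {self.name!r}: parent links contain a cycle"
            )

    def __contains__(self, iri: str) -> bool:
        return iri in self.terms

    def label_of(self, iri: str) -> str:
        try:
            return self.terms[iri].label
        except KeyError:
            raise OntologyTermError(
                f"term {iri!r} not in snapshot {self.name!r} "
                f"(version {self.version})"
            ) from None

    def is_descendant(self, iri: str, ancestor_iri: str) -> bool:
        """True iff ``ancestor_iri`` is reachable from ``iri`` via one or
        more parent links.  Strict: a term is not its own descendant."""
        if iri not in self.terms:
            raise OntologyTermError(
                f"term {iri!r} not in snapshot {self.name!r}"
            )
        queue = deque(self.terms[iri].parent_iris)
        seen: set[str] = set()
        while queue:
            cur = queue.popleft()
            if cur == ancestor_iri:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(self.terms[cur].parent_iris)
        return False


@dataclass
class RegistrySet:
    """The full offline registry bundle used by validation and augmentation."""

    curies: dict[str, CurieEntry] = field(default_factory=dict)
    assemblies: list[AssemblyEntry] = field(default_factory=list)
    ontologies: dict[str, OntologySnapshot] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for entry in self.assemblies:
            names = [entry.canonical_name] + [s for s, _ in entry.synonyms]
            for name in names:
                if name in seen:
                    raise ConfigurationError(
                        f"assembly name {name!r} registered twice"
                    )
                seen.add(name)


def parse_curie(s: str) -> tuple[str, str]:
    """Split a compact identifier at its first colon.

    Raises :class:`CurieSyntaxError` when there is no colon or either part
    is empty.
    """
    prefix, sep, accession = s.partition(":")
    if not sep or not prefix or not accession:
        raise CurieSyntaxError(f"not a prefix:accession compact id: {s!r}")
    return prefix, accession


def resolve_curie(curie: str, registry: RegistrySet) -> str:
    """Expand a CURIE to a URL using the registry's template for its prefix."""
    prefix, accession = parse_curie(curie)
    entry = registry.curies.get(prefix)
    if entry is None:
        raise CuriePrefixError(f"prefix {prefix!r} is not registered")
    if not re.fullmatch(entry.accession_pattern, accession):
        raise CurieAccessionError(
            f"accession {accession!r} does not match the registered "
            f"pattern for prefix {prefix!r}"
        )
    return entry.url_template.replace("{accession}", accession)


def validate_doi(s: str) -> bool:
    """True iff ``s`` is a DOI of the shape ``10.<registrant>/<suffix>``.

    An optional leading ``doi:`` scheme and surrounding whitespace are
    stripped before matching.
    """
    s = s.strip()
    if s.lower().startswith("doi:"):
        s = s[4:]
    return bool(_DOI_RE.match(s))


def normalize_assembly(name: str, registry: RegistrySet) -> tuple[str, str]:
    """Map an assembly name or registered synonym to (canonical, scheme).

    Canonical names report the reference-consortium scheme ``grc``;
    synonyms report their recorded scheme (e.g. ``hg19`` -> ``ucsc``).
    """
    for entry in registry.assemblies:
        if name == entry.canonical_name:
            return entry.canonical_name, "grc"
        for synonym, scheme in entry.synonyms:
            if name == synonym:
                return entry.canonical_name, scheme
    raise UnknownAssemblyError(f"assembly name {name!r} is not registered")


def assembly_entry_for(name: str, registry: RegistrySet) -> AssemblyEntry:
    """The registry row owning ``name`` (canonical or synonym)."""
    canonical, _ = normalize_assembly(name, registry)
    for entry in registry.assemblies:
        if entry.canonical_name == canonical:
            return entry
    raise UnknownAssemblyError(name)  # pragma: no cover - unreachable


# ---------------------------------------------------------------------------
# TSV (de)serialization
# ---------------------------------------------------------------------------

def _read_tsv(path: Path) -> list[list[str]]:
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigurationError(f"cannot read registry file {path}: {exc}")
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_curie_registry(path: Path) -> dict[str, CurieEntry]:
    rows = _read_tsv(path)
    if not rows or rows[0][:1] != ["prefix"]:
        raise ConfigurationError(f"{path}: expected 'prefix' header")
    entries = {}
    for prefix, pattern, template in rows[1:]:
        entries[prefix] = CurieEntry(prefix, pattern, template)
    return entries


def load_assembly_registry(path: Path) -> list[AssemblyEntry]:
    rows = _read_tsv(path)
    if not rows or rows[0][:1] != ["canonical"]:
        raise ConfigurationError(f"{path}: expected 'canonical' header")
    by_canonical: dict[str, dict] = {}
    order: list[str] = []
    for canonical, synonym, scheme, curie in rows[1:]:
        rec = by_canonical.setdefault(canonical, {"curie": curie, "syns": []})
        if canonical not in order:
            order.append(canonical)
        if synonym and synonym != "-":
            rec["syns"].append((synonym, scheme))
    return [
        AssemblyEntry(c, tuple(by_canonical[c]["syns"]), by_canonical[c]["curie"])
        for c in order
    ]


def load_ontology_snapshot(path: Path) -> OntologySnapshot:
    """Read one snapshot TSV.

    Line 1 is a metadata comment ``#name=<name>\tversion=<version>``; the
    body has columns ``iri``, ``label``, ``parents`` (pipe-separated).
    """
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise ConfigurationError(f"cannot read ontology file {path}: {exc}")
    if not lines or not lines[0].startswith("#name="):
        raise ConfigurationError(f"{path}: missing '#name=' metadata line")
    meta = dict(
        part.lstrip("#").split("=", 1) for part in lines[0].split("\t")
    )
    terms = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#") or line.startswith("iri\t"):
            continue
        iri, label, parents = line.split("\t")
        parent_iris = tuple(p for p in parents.split("|") if p)
        terms.append(OntologyTerm(iri, label, parent_iris))
    return OntologySnapshot(meta["name"], meta["version"], terms)


def dump_registry_dir(registry: RegistrySet, directory: Path) -> None:
    """Write a registry bundle as the TSV layout ``load_registry_dir`` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["prefix\tpattern\turl_template"]
    for entry in registry.curies.values():
        lines.append(
            f"{entry.prefix}\t{entry.accession_pattern}\t{entry.url_template}"
        )
    (directory / "curie_registry.tsv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )

    lines = ["canonical\tsynonym\tscheme\tcurie"]
    for entry in registry.assemblies:
        if not entry.synonyms:
            lines.append(f"{entry.canonical_name}\t-\tgrc\t{entry.assembly_curie}")
        for synonym, scheme in entry.synonyms:
            lines.append(
                f"{entry.canonical_name}\t{synonym}\t{scheme}\t"
                f"{entry.assembly_curie}"
            )
    (directory / "assemblies.tsv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )

    for snapshot in registry.ontologies.values():
        lines = [
            f"#name={snapshot.name}\tversion={snapshot.version}",
            "iri\tlabel\tparents",
        ]
        for term in snapshot.terms.values():
            lines.append(f"{term.iri}\t{term.label}\t{'|'.join(term.parent_iris)}")
        (directory / f"ontology_{snapshot.name}.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )


def load_registry_dir(directory: Path) -> RegistrySet:
    """Load a registry bundle written by :func:`dump_registry_dir`."""
    directory = Path(directory)
    curies = load_curie_registry(directory / "curie_registry.tsv")
    assemblies = load_assembly_registry(directory / "assemblies.tsv")
    ontologies = {}
    for path in sorted(directory.glob("ontology_*.tsv")):
        snapshot = load_ontology_snapshot(path)
        ontologies[snapshot.name] = snapshot
    return RegistrySet(curies, assemblies, ontologies)


_DEFAULT: RegistrySet | None = None


def default_registries() -> RegistrySet:
    """The packaged offline registry bundle (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        from .fixtures import make_fixture_registries

        _DEFAULT = make_fixture_registries()
    return _DEFAULT
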