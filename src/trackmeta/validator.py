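"""Full document validation: schema conformance plus document-set rules.

All problems accumulate into a deterministic :class:`ValidationReport`;
nothing fails fast.  Unknown extra fields never produce issues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import jsonschema

from . import registries as reg
from . import schema as sch
from .errors import (
    CurieAccessionError,
    CuriePrefixError,
    CurieSyntaxError,
    UnknownAssemblyError,
)
from .model import FairDocument, canonical_dumps

RULE_KINDS = (
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


@dataclass(frozen=True)
class ValidationIssue:
    rule_kind: str
    path: str
    message: str

    def to_obj(self) -> dict:
        return {"rule_kind": self.rule_kind, "path": self.path,
                "message": self.message}


@dataclass
class ValidationReport:
    """Ordered list of rule violations; ``ok`` iff there are none.

    Ordering is (path, rule_kind, message) lexicographic, which makes the
    serialized report byte-stable for identical inputs.
    """

    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_obj(self) -> dict:
        return {"ok": self.ok, "issues": [i.to_obj() for i in self.issues]}

    def to_json(self) -> str:
        return canonical_dumps(self.to_obj())

    def to_text(self) -> str:
        if self.ok:
            return "OK: no issues found\n"
        lines = [f"{len(self.issues)} issue(s) found:"]
        lines += [f"  [{i.rule_kind}] {i.path}: {i.message}"
                  for i in self.issues]
        return "\n".join(lines) + "\n"

    def kinds(self) -> set:
        return {i.rule_kind for i in self.issues}


def _dotted_values(owner, dotted: str):
    """Yield (path_suffix, value) for a dotted field path; '[]' expands a
    list field into its elements."""
    listwise = dotted.endswith("[]")
    parts = dotted.removesuffix("[]").split(".")
    node = owner
    suffix = ""
    for part in parts:
        if node is None:
            return
        node = getattr(node, part)
        suffix += f"/{part}"
    if node is None:
        return
    if listwise:
        for i, elem in enumerate(node):
            yield f"{suffix}/{i}", elem
    else:
        yield suffix, node


def _iter_constraints(doc: FairDocument, table):
    """Expand a constraint table over a document.

    Yields (json-pointer path, value, *rest-of-row) for every present value.
    """
    for row in table:
        list_name, dotted = row[0], row[1]
        for idx, owner in enumerate(getattr(doc, list_name)):
            for suffix, value in _dotted_values(owner, dotted):
                yield f"/{list_name}/{idx}{suffix}", value, *row[2:]


class DocumentValidator:
    """Validates documents against the schema plus the document-set rules.

    Parameters
    ----------
    registries:
        Registry bundle to check CURIEs, assembly names and ontology terms
        against; defaults to the packaged offline bundle.
    """

    def __init__(self, registries: reg.RegistrySet | None = None):
        self.registries = registries or reg.default_registries()
        self._schema = sch.build_schema()
        self._schema_validator = jsonschema.Draft7Validator(self._schema)

    # -- individual rule groups (each returns a list of issues) -------------

    def _check_schema(self, doc: FairDocument):
        issues = []
        for error in self._schema_validator.iter_errors(doc.to_obj()):
            path = "/" + "/".join(str(p) for p in error.absolute_path)
            issues.append(ValidationIssue("schema", path, error.message))
        return issues

    def _check_unique(self, doc: FairDocument):
        issues = []
        for list_name, field_name in sch.UNIQUE_FIELDS:
            seen: dict[str, int] = {}
            for idx, obj in enumerate(getattr(doc, list_name)):
                value = getattr(obj, field_name)
                if value is None:
                    continue
                if value in seen:
                    issues.append(ValidationIssue(
                        "unique_violation",
                        f"/{list_name}/{idx}/{field_name}",
                        f"{field_name} {value!r} already used at "
                        f"/{list_name}/{seen[value]}",
                    ))
                else:
                    seen[value] = idx
        return issues

    def _check_foreign_refs(self, doc: FairDocument):
        ids = {
            list_name: {obj.local_id for obj in getattr(doc, list_name)
                        if obj.local_id is not None}
            for list_name in ("collections", "studies", "samples",
                              "experiments", "tracks")
        }
        issues = []
        for path, value, target in _iter_constraints(doc, sch.FOREIGN_REFS):
            if not value:
                continue
            if value not in ids[target]:
                issues.append(ValidationIssue(
                    "foreign_ref", path,
                    f"reference {value!r} does not resolve within "
                    f"{target!r}",
                ))
        return issues

    def check_aggregation_acyclic(self, doc: FairDocument):
        """Flag every experiment on a directed cycle of aggregated_from
        links.  Unresolvable references are ignored here (foreign-ref rule
        reports them)."""
        known = {e.local_id for e in doc.experiments if e.local_id}
        graph = {
            e.local_id: [t for t in (e.aggregated_from or []) if t in known]
            for e in doc.experiments if e.local_id
        }
        on_cycle = cycle_nodes(graph)
        issues = []
        for idx, exp in enumerate(doc.experiments):
            if exp.local_id in on_cycle:
                issues.append(ValidationIssue(
                    "aggregation_cycle",
                    f"/experiments/{idx}/aggregated_from",
                    f"experiment {exp.local_id!r} participates in an "
                    f"aggregation cycle",
                ))
        return issues

    def _check_curies(self, doc: FairDocument):
        issues = []
        for path, value, allowed in _iter_constraints(
            doc, sch.CURIE_FIELD_CONSTRAINTS
        ):
            if hasattr(value, "term_id"):  # gene_id is a CURIE+label pair
                path += "/term_id"
                value = value.term_id
            if not value:
                continue
            try:
                prefix, _ = reg.parse_curie(value)
                if allowed and prefix not in allowed:
                    raise CuriePrefixError(
                        f"prefix {prefix!r} not allowed here "
                        f"(expected one of {sorted(allowed)})"
                    )
                reg.resolve_curie(value, self.registries)
            except (CurieSyntaxError, CuriePrefixError,
                    CurieAccessionError) as exc:
                issues.append(ValidationIssue(exc.kind, path, str(exc)))
        return issues

    def check_ontology_fields(self, doc: FairDocument,
                              snapshots: dict | None = None,
                              constraint_table=None):
        """Term existence, ancestor constraints and label consistency for
        every ontology-constrained field.  Labels are augmentation-owned
        and therefore optional; a present label must match the snapshot."""
        snapshots = snapshots if snapshots is not None \
            else self.registries.ontologies
        table = constraint_table or sch.TERM_FIELD_CONSTRAINTS
        issues = []
        for path, pair, ontology, ancestors in _iter_constraints(doc, table):
            term_id = pair.term_id
            if not term_id:
                continue  # presence is the schema's concern
            snapshot = snapshots.get(ontology)
            if snapshot is None:
                continue
            if term_id not in snapshot:
                issues.append(ValidationIssue(
                    "ontology_term", f"{path}/term_id",
                    f"term {term_id!r} not found in ontology "
                    f"{ontology!r} (version {snapshot.version})",
                ))
                continue
            for ancestor in ancestors:
                if not snapshot.is_descendant(term_id, ancestor):
                    issues.append(ValidationIssue(
                        "ontology_ancestor", f"{path}/term_id",
                        f"term {term_id!r} does not descend from required "
                        f"ancestor {ancestor!r}",
                    ))
            expected = snapshot.label_of(term_id)
            if pair.term_label is not None and pair.term_label != expected:
                issues.append(ValidationIssue(
                    "ontology_label_mismatch", f"{path}/term_label",
                    f"label {pair.term_label!r} does not match snapshot "
                    f"label {expected!r}",
                ))
        return issues

    def _check_assemblies(self, doc: FairDocument):
        issues = []
        for idx, track in enumerate(doc.tracks):
            name, accession = track.annotation_name, track.assembly_id
            if not name or not accession:
                continue
            path = f"/tracks/{idx}/annotation_name"
            try:
                entry = reg.assembly_entry_for(name, self.registries)
            except UnknownAssemblyError as exc:
                issues.append(ValidationIssue("assembly_name", path, str(exc)))
                continue
            if entry.assembly_curie != accession:
                issues.append(ValidationIssue(
                    "assembly_name", path,
                    f"annotation_name {name!r} belongs to assembly "
                    f"{entry.assembly_curie!r}, not {accession!r}",
                ))
        return issues

    def _check_checksums(self, doc: FairDocument):
        issues = []
        for idx, track in enumerate(doc.tracks):
            cs = track.checksum
            if cs is None or cs.method not in sch.CHECKSUM_LENGTHS:
                continue  # missing/unknown method is the schema's concern
            if not cs.value:
                continue
            length = sch.CHECKSUM_LENGTHS[cs.method]
            if not re.fullmatch(rf"[0-9a-f]{{{length}}}", cs.value):
                issues.append(ValidationIssue(
                    "checksum_format", f"/tracks/{idx}/checksum/value",
                    f"{cs.method} checksum must be {length} lowercase hex "
                    f"characters",
                ))
        return issues

    def _check_doi(self, doc: FairDocument):
        issues = []
        info = doc.doc_info
        if info is not None and info.doi and not reg.validate_doi(info.doi):
            issues.append(ValidationIssue(
                "doi_format", "/doc_info/doi",
                f"{info.doi!r} is not a valid DOI",
            ))
        return issues

    def _check_biospecimen(self, doc: FairDocument):
        issues = []
        for idx, sample in enumerate(doc.samples):
            cls = sample.biospecimen_class
            if cls is None or cls.term_id not in sch.BIOSPECIMEN_CLASSES:
                continue  # closed set is enforced by the schema
            label, child = sch.BIOSPECIMEN_CLASSES[cls.term_id]
            if sample.sample_type is None or \
                    getattr(sample.sample_type, child) is None:
                issues.append(ValidationIssue(
                    "biospecimen_child_missing",
                    f"/samples/{idx}/sample_type",
                    f"biospecimen_class {label!r} requires the "
                    f"sample_type child {child!r}",
                ))
        return issues

    def _check_cardinality(self, doc: FairDocument):
        issues = []
        for idx, exp in enumerate(doc.experiments):
            has_sample = bool(exp.sample_ref)
            agg = exp.aggregated_from or []
            if has_sample == bool(agg):
                issues.append(ValidationIssue(
                    "cardinality", f"/experiments/{idx}",
                    "exactly one of sample_ref and aggregated_from must "
                    "be used",
                ))
            if len(agg) != len(set(agg)):
                issues.append(ValidationIssue(
                    "cardinality", f"/experiments/{idx}/aggregated_from",
                    "aggregated_from contains duplicate references",
                ))
        return issues

    # -- entry point --------------------------------------------------------

    def validate(self, doc: FairDocument) -> ValidationReport:
        issues = []
        issues += self._check_schema(doc)
        issues += self._check_unique(doc)
        issues += self._check_foreign_refs(doc)
        issues += self.check_aggregation_acyclic(doc)
        issues += self._check_curies(doc)
        issues += self.check_ontology_fields(doc)
        issues += self._check_assemblies(doc)
        issues += self._check_checksums(doc)
        issues += self._check_doi(doc)
        issues += self._check_biospecimen(doc)
        issues += self._check_cardinality(doc)
        issues.sort(key=lambda i: (i.path, i.rule_kind, i.message))
        return ValidationReport(issues)


def cycle_nodes(graph: dict) -> set:
    """Nodes of ``graph`` (adjacency dict) lying on a directed cycle.

    Iterative Tarjan strongly-connected components; a node is on a cycle
    iff its SCC has size > 1 or it has a self-loop.
    """
    index: dict = {}
    lowlink: dict = {}
    on_stack: set = set()
    stack: list = []
    counter = [0]
    result: set = set()

    for root in graph:
        if root in index:
            continue
        work = [(root, iter(graph.get(root, ())))]
        index[root] = lowlink[root] = counter[0]
        counter[0] += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            node, successors = work[-1]
            advanced = False
            for succ in successors:
                if succ not in graph:
                    continue
                if succ not in index:
                    index[succ] = lowlink[succ] = counter[0]
                    counter[0] += 1
                    stack.append(succ)
                    on_stack.add(succ)
                    work.append((succ, iter(graph.get(succ, ()))))
                    advanced = True
                    break
                if succ in on_stack:
                    lowlink[node] = min(lowlink[node], index[succ])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                lowlink[parent] = min(lowlink[parent], lowlink[node])
            if lowlink[node] == index[node]:
                scc = []
                while True:
                    member = stack.pop()
                    on_stack.discard(member)
                    scc.append(member)
                    if member == node:
                        break
                if len(scc) > 1:
                    result.update(scc)
                elif scc[0] in graph.get(scc[0], ()):
                    result.add(scc[0])  # self-loop
    return result


def validate_document(doc: FairDocument,
                      registries: reg.RegistrySet | None = None
                      ) -> ValidationReport:
    """Convenience wrapper around :class:`DocumentValidator`."""
    return DocumentValidator(registries).validate(doc)
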