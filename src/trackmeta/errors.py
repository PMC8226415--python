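"""Exception hierarchy shared across the package."""

from __future__ import annotations


class TrackMetaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TrackMetaError):
    """Malformed JSON input; carries line/column of the failure."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class StructureError(TrackMetaError):
    """Well-formed JSON whose shape cannot be mapped onto the model."""


class RegistryError(TrackMetaError):
    """Base class for identifier / ontology registry errors."""


class CurieSyntaxError(RegistryError):
    kind = "curie_syntax"


class CuriePrefixError(RegistryError):
    kind = "curie_prefix"


class CurieAccessionError(RegistryError):
    kind = "curie_accession"


class UnknownAssemblyError(RegistryError):
    kind = "assembly_name"


class OntologyTermError(RegistryError):
    kind = "ontology_term"


class OntologyCycleError(RegistryError):
    """Raised at snapshot load time when parent links form a cycle."""


class ConfigurationError(TrackMetaError):
    """Registry files missing or unreadable."""


class AugmentationRefusedError(TrackMetaError):
    """Augmentation requires a clean validation report.

    Carries the blocking :class:`~trackmeta.validator.ValidationReport`.
    """

    def __init__(self, report):
        lines = "; ".join(
            f"{i.rule_kind} at {i.path}" for i in report.issues[:5]
        )
        more = "" if len(report.issues) <= 5 else f" (+{len(report.issues) - 5} more)"
        super().__init__(f"document does not validate: {lines}{more}")
        self.report = report


class BiospecimenChildMissingError(TrackMetaError):
    """The sample_type child selected by biospecimen_class is absent."""


class TargetChildMissingError(TrackMetaError):
    """The technique's summary recipe demands a target child that is absent."""


class GSuiteFormatError(TrackMetaError):
    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (line {line})")
        self.line = line


class HubFormatError(TrackMetaError):
    """Track-hub stanza files could not be parsed."""
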