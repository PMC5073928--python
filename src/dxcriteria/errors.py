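"""Exception hierarchy shared across the package."""


class DxCriteriaError(Exception):
    """Base class for all package errors."""


class InvalidNameError(DxCriteriaError):
    """A raw display name cannot be turned into an identifier."""


class OntologyError(DxCriteriaError):
    """An edit would violate an ontology invariant."""


class HqmfParseError(DxCriteriaError):
    """An HQMF document is malformed or does not follow the template shape."""


class UnsupportedTemplateError(HqmfParseError):
    """A templateId OID outside the supported template inventory."""

    def __init__(self, oid: str):
        self.oid = oid
        super().__init__(f"unsupported HQMF template OID: {oid}")


class TitleFormatError(HqmfParseError):
    """A criterion <title> does not follow '{datatype}: {value set}'."""


class ComparisonFormatError(HqmfParseError):
    """A result-comparison observation lacks a usable bound."""


class CriterionSyntaxError(DxCriteriaError):
    """A textual criterion string does not match the grammar."""

    def __init__(self, message: str, text: str, position: int = 0):
        self.text = text
        self.position = position
        super().__init__(f"{message} (at position {position}): {text!r}")


class UnknownDatatypeError(DxCriteriaError):
    """A criterion names a datatype with no QDM class in the upper ontology."""

    def __init__(self, datatype_name: str, known: list[str]):
        self.datatype_name = datatype_name
        self.known = list(known)
        super().__init__(
            f"unknown QDM datatype {datatype_name!r}; known datatypes: "
            + ", ".join(sorted(self.known))
        )


class CompositionError(DxCriteriaError):
    """Rule composition requires ontology elements that are missing."""


class UsageError(DxCriteriaError):
    """An operation was called with out-of-contract arguments."""
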