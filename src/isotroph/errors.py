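"""Exception hierarchy for the isotroph pipeline."""


class IsotrophError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IsotrophError):
    """A required column or field is missing from an input table."""


class ParseError(IsotrophError):
    """A cell could not be parsed as the required type; carries the row number."""


class ValidationError(IsotrophError):
    """A domain invariant is violated (non-finite delta, asymmetric matrix, ...)."""


class AlignmentError(IsotrophError):
    """Label sets of compared structures have an empty intersection or mismatch."""


class CodingError(IsotrophError):
    """A prey category has no trophic rank in the coding table."""


class AnalysisError(IsotrophError):
    """A statistical operation is undefined for the given input (zero variance, ...)."""
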