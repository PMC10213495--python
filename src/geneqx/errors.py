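"""Exception hierarchy shared across the package."""


class GeneqxError(Exception):
    """Base class for all geneqx errors."""


class FormatError(GeneqxError):
    """A file does not conform to the documented dialect (e.g. missing column)."""


class ParseError(GeneqxError):
    """A field could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(GeneqxError):
    """Input violates a documented precondition."""


class MissingVariantError(GeneqxError):
    """A model variant is absent from the frequency panel; names the variant."""


class DegenerateGeneError(GeneqxError):
    """VA is zero (all model variants fixed across populations); the gene must be skipped."""


class SingularCovarianceError(GeneqxError):
    """The neutral covariance matrix F is singular beyond tolerance."""
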