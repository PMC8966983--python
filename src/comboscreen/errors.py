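"""Exception hierarchy shared across the package."""


class ComboScreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ComboScreenError, ValueError):
    """An input value violates a documented precondition."""


class PlateFormatError(ComboScreenError):
    """A plate file is structurally malformed (e.g. missing columns)."""


class NormalizationError(ComboScreenError):
    """Control-based normalization is impossible (no usable control wells)."""


class GridAssemblyError(ComboScreenError):
    """Wells do not cover the full dose cross needed for a combination grid."""

    def __init__(self, message, missing_pairs=()):
        super().__init__(message)
        self.missing_pairs = tuple(missing_pairs)


class FitError(ComboScreenError):
    """A dose-response or surface fit cannot be run on the given data."""


class DoseRangeError(ComboScreenError):
    """A surface query lies outside the measured dose range."""


class RegimenUndefinedError(ComboScreenError):
    """No computed (uncensored, reached) CI values exist to minimize over."""


class StratumError(ComboScreenError):
    """A differential contrast has too few samples in one arm."""


class EmptyAnalysisError(ComboScreenError):
    """A filtering step removed every antibody."""


class PairingError(ComboScreenError, ValueError):
    """Paired metric vectors have mismatched lengths or too few entries."""


class ComparisonError(ComboScreenError):
    """A group comparison has a group that is too small."""


class ClassificationError(ComboScreenError):
    """Sensitivity classification lacks enough uncensored IC50s."""


class GeneratorError(ComboScreenError):
    """A synthetic-data generator failed to converge or was misconfigured."""
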