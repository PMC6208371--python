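"""Exception hierarchy shared across the pipeline."""


class SensiscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(SensiscreenError):
    """A required column or config key is missing or malformed."""


class CoordinateError(SensiscreenError):
    """A well coordinate falls outside the 96-well A1..H12 grid."""


class LinkageError(SensiscreenError):
    """A measurement references a well absent from every plate map."""


class InsufficientControlsError(SensiscreenError):
    """Fewer than two negative- or positive-control wells on a plate."""


class UndefinedSSMDError(SensiscreenError):
    """Both control groups are degenerate (zero spread, equal means)."""


class DegenerateNormalizationError(SensiscreenError):
    """Negative-control spread is zero; z-scores are undefined."""


class MissingArmError(SensiscreenError):
    """An operation needs both vehicle and drug arms but one is absent."""


class EmptyResultsError(SensiscreenError):
    """Asked to serialize an empty result collection."""


class FitError(SensiscreenError):
    """A curve fit failed or its inputs are unusable."""


class DegenerateFitError(FitError):
    """Response data carry no dose dependence to fit."""


class SizingError(SensiscreenError):
    """The plate layout cannot host the requested library."""
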