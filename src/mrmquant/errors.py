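"""Exception hierarchy for mrmquant.

Every error raised by the package derives from :class:`MrmQuantError` so
callers (and the CLI) can catch one base class.
"""


class MrmQuantError(Exception):
    """Base class for all mrmquant errors."""


class ConfigError(MrmQuantError):
    """Invalid assay or simulation configuration."""


class SchemaError(MrmQuantError):
    """A table is missing required columns or has an invalid layout."""


class DegenerateDesignError(MrmQuantError):
    """Too few distinct concentration levels to fit the requested model."""


class WeightingDomainError(MrmQuantError):
    """A nominal concentration is incompatible with 1/x-family weighting."""


class FitRejectedError(MrmQuantError):
    """The fitted response is not strictly increasing over the range."""


class UndefinedRatioError(MrmQuantError):
    """Analyte/IS ratio undefined (internal-standard area is zero)."""


class InversionError(MrmQuantError):
    """No admissible root when inverting a calibration curve."""


class InvalidReferenceError(MrmQuantError):
    """A reference mean (LLOQ or IS response) is zero or missing."""


class InsufficientReplicatesError(MrmQuantError):
    """Fewer replicates than the statistic requires."""


class DesignIncompleteError(MrmQuantError):
    """A validation battery is missing required design cells."""

    def __init__(self, message: str, gaps: list[str] | None = None):
        super().__init__(message)
        self.gaps = gaps or []


class PairingError(MrmQuantError):
    """Matrix lots (or acid/lactone partners) cannot be matched up."""


class UndefinedProportionError(MrmQuantError):
    """Acid and lactone concentrations are both zero."""


class InsufficientPairsError(MrmQuantError):
    """Too few complete patient pairs for a correlation."""


class CollinearityError(MrmQuantError):
    """A regression covariate is constant (or collinear)."""
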