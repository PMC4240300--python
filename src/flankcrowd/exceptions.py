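"""Exception hierarchy for flankcrowd.

All package-specific failures derive from :class:`FlankCrowdError` so callers
can catch one base class; fine-grained subclasses mirror the validation
contracts of each pipeline stage.
"""


class FlankCrowdError(Exception):
    """Base class for all flankcrowd errors."""


class GeometryError(FlankCrowdError):
    """Invalid viewing geometry (non-positive distance, angle >= 180 deg, ...)."""


class GeometryOverflowError(GeometryError):
    """A composed stimulus does not fit inside its fixation box."""


class ExcludedSymbolError(FlankCrowdError):
    """A letter outside the permitted target alphabet was used as a target."""


class InvalidFlankerError(FlankCrowdError):
    """A flanker symbol outside the task's flanker pool (e.g. digit not in 2-9)."""


class UndefinedSimilarityError(FlankCrowdError):
    """Similarity requested against a blank (ink-free) image."""


class InvalidResponseError(FlankCrowdError):
    """A response symbol that is neither a permitted letter nor the no-response token."""


class InvalidLatencyError(FlankCrowdError):
    """Non-positive latency passed to the inverse transformation."""


class DegenerateRangeError(FlankCrowdError):
    """Score standardisation attempted on a constant score vector."""


class DegenerateCovariateError(FlankCrowdError):
    """Covariate adjustment attempted with a constant covariate."""


class WrongErrorClassError(FlankCrowdError):
    """A correct or Type A trial passed where only Type B/C errors are allowed."""


class InconsistentDesignError(FlankCrowdError):
    """Model comparison attempted across fits built from different trial sets."""


class RobustSEError(FlankCrowdError):
    """Cluster-robust standard errors requested with fewer than two clusters."""


class ConfigError(FlankCrowdError):
    """Configuration failed schema validation."""


class MissingColumnError(FlankCrowdError):
    """A required column is absent from a trial table."""


class SeparationWarning(UserWarning):
    """Quasi-separation detected during a logistic fit; a penalised fallback was used."""
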