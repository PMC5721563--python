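"""Exception hierarchy for valvemorph.

All package errors derive from :class:`ValvemorphError` so callers can
catch the whole family with one clause.
"""


class ValvemorphError(Exception):
    """Base class for all valvemorph errors."""


class FormatError(ValvemorphError):
    """A file does not conform to its declared dialect."""


class ConsistencyError(ValvemorphError):
    """Records that must agree (landmark counts, label parallelism) do not."""


class DegenerateConfigurationError(ValvemorphError):
    """A landmark configuration has no usable geometry (e.g. zero centroid size)."""


class ShapeMismatchError(ValvemorphError):
    """Two configurations that must share a landmark scheme do not."""


class InsufficientOverlapError(ValvemorphError):
    """Too few species shared between tree and shape data."""


class AlignmentError(ValvemorphError):
    """Species order of a data matrix does not match the phylogenetic covariance."""


class NearSingularError(ValvemorphError):
    """Phylogenetic covariance is numerically singular (e.g. zero-length cherry)."""


class PairingError(ValvemorphError):
    """Left/right valves cannot be paired per specimen."""


class MissingDistributionError(ValvemorphError):
    """A permutation distribution required for an effect-size comparison is absent."""


class DesignError(ValvemorphError):
    """A model design matrix is invalid (empty group, collinearity)."""


class ConfigError(ValvemorphError):
    """Invalid generator or analysis configuration."""
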