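"""Exception hierarchy.

All package errors derive from :class:`DVMError` so callers can catch one
type; subclasses distinguish configuration mistakes from degenerate data.
"""


class DVMError(Exception):
    """Base class for all dvmetric errors."""


class InputError(DVMError, ValueError):
    """Malformed input data (non-finite values, empty samples, wrong kind)."""


class PairedSampleError(InputError):
    """Sample vectors that must be paired have different lengths."""


class ParameterError(DVMError, ValueError):
    """An estimator or algorithm parameter is out of range (e.g. k >= n)."""


class ConfigError(DVMError, ValueError):
    """Invalid configuration (unknown estimator id, bad split fractions...)."""


class MissingCostError(ConfigError):
    """A model whose training complexity 'varies' was used without an
    explicit user-supplied cost function."""


class DegenerateDataError(DVMError, ValueError):
    """Data degenerate for the requested computation."""


class DegenerateSignalError(DegenerateDataError):
    """The full-data mutual information I(X;Y) fell below the positive
    floor that guards the fidelity denominator."""


class DegenerateLabelError(DegenerateDataError):
    """Labels carry no usable variation (e.g. a single class)."""


class DegenerateClusteringError(DegenerateDataError):
    """A clustering step returned a single cluster, so cluster-stability
    mutual information is undefined."""


class BoundsError(DVMError, ValueError):
    """A requested grid or subsample exceeds the dataset's dimensions."""
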