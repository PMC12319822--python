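"""Exception hierarchy.

Three error classes cover the contract failures the pipeline
distinguishes: bad configuration (caught before any data are touched),
bad inputs (shape/content violations at call time), and numerical
degeneracies (rank-deficient covariances, non-positive baselines).
"""


class GammaflowError(Exception):
    """Base class for all gammaflow errors."""


class ConfigError(GammaflowError):
    """A configuration value violates its documented constraint."""


class InputError(GammaflowError):
    """Input data violate a precondition (shape, emptiness, range)."""


class NumericalError(GammaflowError):
    """A numerically degenerate quantity was encountered."""
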