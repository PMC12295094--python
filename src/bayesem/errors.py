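"""Exception hierarchy.

All package-specific failures derive from :class:`BayesemError` so callers can
catch one base class; configuration and dimension problems are ``ValueError``
subclasses, numerical breakdowns are not.
"""


class BayesemError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BayesemError, ValueError):
    """Invalid basis / optimizer / hyperparameter configuration."""


class DimensionError(BayesemError, ValueError):
    """Shape mismatch between hyperparameters, design matrix and targets."""


class UnsupportedBasisError(ConfigError):
    """Basis family cannot be applied to the given input (e.g. polynomial on vectors)."""


class NumericalError(BayesemError):
    """Non-finite values encountered in a linear-algebra step."""


class DegenerateFitError(BayesemError):
    """An M-step denominator vanished (noise precision or weight precision undefined)."""


class DegeneratePredictionError(BayesemError):
    """Predictive variance non-positive (pseudo-inverse covariance artifact)."""


class ParseError(BayesemError, ValueError):
    """Malformed delimited-text input."""
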