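"""Exception hierarchy shared across the package."""


class T2DRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(T2DRiskError):
    """Invalid configuration (counts, rates, unknown feature references)."""


class DataError(T2DRiskError):
    """Input data violates a documented contract."""


class InputError(T2DRiskError):
    """Invalid argument to a numerical primitive."""


class MetricError(T2DRiskError):
    """A metric is undefined for the given input (e.g. single-class labels)."""


class SplitError(T2DRiskError):
    """A grouped split cannot be constructed."""


class SelectionError(T2DRiskError):
    """Feature selection received an unusable starting set."""
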