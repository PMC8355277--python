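"""Exception types shared across the pipeline."""


class VDGradientError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VDGradientError, ValueError):
    """An input value is outside its scientific domain (e.g. probability > 1)."""


class CoverageError(VDGradientError, ValueError):
    """An analysis window falls outside the recorded span of one or more trials."""


class ConfigError(VDGradientError, ValueError):
    """An invalid configuration (schema violation, non-PSD correlation target, ...)."""


class CollinearityError(VDGradientError, ValueError):
    """Regressors supplied to a per-neuron regression are (near-)collinear."""


class DegenerateDataError(VDGradientError, ValueError):
    """Data lack the variance needed for the requested statistic."""
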