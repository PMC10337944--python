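"""Exception hierarchy for netmr."""


class NetMRError(Exception):
    """Base class for all netmr errors."""


class ConfigError(NetMRError):
    """Invalid configuration: missing columns, unknown keys, bad schema."""


class SumstatsError(NetMRError):
    """A summary-statistics file could not be used (too many bad rows, ...)."""


class NoInstrumentsError(NetMRError):
    """No variant survived instrument selection at the given p threshold."""


class HarmonizationError(NetMRError):
    """Exposure and outcome summary statistics share no usable variants."""


class InsufficientInstrumentsError(NetMRError):
    """An estimator was given fewer SNPs than its minimum."""


class DegenerateInstrumentError(NetMRError):
    """Wald ratio requested for an instrument with zero exposure effect."""


class CollinearityError(NetMRError):
    """The multivariable exposure-effect matrix is rank deficient."""


class EstimationError(NetMRError):
    """An iterative estimator failed to converge or to bracket a root."""


class UndefinedMediationError(NetMRError):
    """Proportion mediated is undefined (zero total effect)."""
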