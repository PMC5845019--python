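"""Exception hierarchy shared across the pipeline stages."""


class NirspipeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NirspipeError, ValueError):
    """An argument violates a stage's preconditions."""


class LayoutMismatchError(NirspipeError):
    """A probe layout does not match what an operation requires."""


class DegenerateChannelError(NirspipeError):
    """A channel is constant (zero variance) and cannot be normalized."""


class RankDeficiencyError(NirspipeError):
    """A design matrix is rank deficient."""


class EmptySelectionError(NirspipeError):
    """No task-unrelated channels survived the correlation threshold."""


class ConfigError(NirspipeError, ValueError):
    """A configuration file or mapping failed validation."""


class FormatError(NirspipeError, ValueError):
    """A data file is malformed; the message carries the offending line."""
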