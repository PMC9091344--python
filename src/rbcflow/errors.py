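"""Exception hierarchy shared across the pipeline.

Exit-code convention for the CLI: input/format problems exit with 2,
degenerate-data conditions (empty bins, undefined ratios) exit with 3.
"""


class RBCFlowError(Exception):
    """Base class for all package errors."""


class FormatError(RBCFlowError):
    """A file or directory does not have the expected on-disk format."""

    exit_code = 2


class ConfigurationError(RBCFlowError):
    """A configuration value is missing, inconsistent, or physically impossible."""

    exit_code = 2


class RejectedInputError(RBCFlowError, ValueError):
    """An operation received input outside its contract (bad label, bad range, NaN crop)."""

    exit_code = 2


class DegenerateDataError(RBCFlowError):
    """Data are valid but too degenerate for the requested statistic."""

    exit_code = 3


class EmptyBinError(DegenerateDataError):
    """A velocity bin holds no tracks; a density cannot be estimated."""


class UndefinedRatioError(DegenerateDataError):
    """A count ratio has a zero denominator; reported as null, never infinity."""


class UndefinedScoreError(DegenerateDataError):
    """Sample and reference share no populated velocity bins."""
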