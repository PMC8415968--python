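"""Exception hierarchy shared across the pipeline."""


class CernanetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CernanetError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class FormatError(CernanetError, ValueError):
    """Malformed external input (TSV/GMT/network files)."""


class DataError(CernanetError, ValueError):
    """Structurally valid input that violates a statistical precondition
    (missing group, zero-library sample, mismatched sample sets, ...)."""


class DomainError(CernanetError, ValueError):
    """Arguments outside the mathematical domain of a statistic."""


class DegenerateFeatureError(CernanetError):
    """A feature with zero variance was passed to a correlation.

    This is a signal, not a failure: callers exclude the affected
    candidate and log it rather than aborting the screen.
    """
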