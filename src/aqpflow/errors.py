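"""Exception hierarchy.

Every error raised by the library derives from :class:`AqpflowError` so
callers can catch the whole family with one clause. Subclasses mark the
stage that failed; messages name the violated invariant or the offending
input.
"""


class AqpflowError(Exception):
    """Base class for all aqpflow errors."""


class ConfigurationError(AqpflowError):
    """A simulation or experiment configuration violates an invariant."""


class DomainError(AqpflowError):
    """A numeric argument is outside the physically meaningful domain."""


class NormalizationError(AqpflowError):
    """A trace cannot be put on the relative signal scale."""


class FitError(AqpflowError):
    """A least-squares fit failed or had insufficient data."""


class WindowError(AqpflowError):
    """No valid fitting window could be located on a trace."""


class AggregationError(AqpflowError):
    """Replicate aggregation left no usable values."""


class ComparisonError(AqpflowError):
    """Two estimates cannot be compared (kind or strain mismatch)."""


class StatisticalTestError(AqpflowError):
    """A statistical test is degenerate (e.g. both groups have zero variance)."""


class AssayError(AqpflowError):
    """A weak-acid accumulation ratio is inconsistent with any intracellular pH."""


class PairingError(AqpflowError):
    """qPCR samples cannot be paired (missing reference-gene well)."""


class InputError(AqpflowError):
    """A user-supplied table or series is malformed (duplicates, too short)."""


class ParseError(AqpflowError):
    """An input file violates the expected dialect; message carries the row."""


class PipelineError(AqpflowError):
    """A pipeline stage aborted; message names the stage and input."""
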