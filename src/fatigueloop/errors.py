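"""Exception hierarchy shared across the pipeline.

Two roots matter for the CLI exit-code contract: :class:`ConfigurationError`
(bad parameters; exit code 2) and :class:`DataError` (bad inputs; exit code 3).
"""


class FatigueLoopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FatigueLoopError, ValueError):
    """A parameter violates a documented bound (CLI exit code 2)."""


class DataError(FatigueLoopError, ValueError):
    """Input data violates a precondition (CLI exit code 3)."""


class SamplingError(ConfigurationError):
    """Sampling rate incompatible with the requested band."""


class LabelingError(DataError):
    """Ground-truth labeling impossible (e.g. missing active-torque baseline)."""


class TrainingError(DataError):
    """Classifier training impossible (e.g. a single class present)."""


class StratificationError(DataError):
    """A class has fewer members than the requested number of folds."""


class TimingError(DataError):
    """Controller stepped with a non-increasing timestamp."""
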