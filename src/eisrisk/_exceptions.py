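"""Shared exception types."""


class EisriskError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(EisriskError, ValueError):
    """A precondition on an argument was violated."""


class FormatError(EisriskError, ValueError):
    """A file or in-memory structure violates the documented schema."""


class AugmentationInfeasibleError(EisriskError, ValueError):
    """SMOTE cannot run on the requested class (fewer than 2 samples)."""


class ConfigurationError(EisriskError, ValueError):
    """An experiment configuration cannot be satisfied by the data."""
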