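"""Exception types shared across the pipeline stages."""


class VfssError(Exception):
    """Base class for all package errors."""


class VideoReadError(VfssError, IOError):
    """A video file or frame directory could not be read."""


class EmptyInputError(VfssError, ValueError):
    """A source decoded to zero frames or had too few frames for an operation."""


class BoundsError(VfssError, IndexError):
    """A requested window exceeds the sequence extent."""


class ContractError(VfssError, ValueError):
    """An input violates a stage precondition (e.g. double normalization)."""


class ConfigError(VfssError, ValueError):
    """An invalid configuration value."""


class DegenerateDataError(VfssError, ValueError):
    """A dataset unusable for the requested operation (e.g. single-class training set)."""
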