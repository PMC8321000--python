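"""Exception and warning types shared across the pipeline."""


class LungCADError(Exception):
    """Base class for all package errors."""


class InputError(LungCADError, ValueError):
    """Invalid or unreadable input."""


class UnsupportedFormatError(InputError):
    """File exists but is not a single-frame 8/16-bit grayscale image."""


class InconsistentSeriesError(InputError):
    """Slices of one series disagree on image dimensions."""


class DegenerateInputError(InputError):
    """Input is degenerate for the requested operation (e.g. constant image)."""


class ConfigError(LungCADError, ValueError):
    """Configuration values are invalid or geometrically infeasible."""


class EmptySegmentationWarning(UserWarning):
    """Segmentation produced an empty mask; the slice may contain no lung."""
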