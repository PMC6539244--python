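"""Exception and warning types shared across the package."""


class DriveStressError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DriveStressError, ValueError):
    """A file does not conform to its expected dialect."""


class EmptyRecordingError(FormatError):
    """A recording contains no samples."""


class OrderingError(FormatError):
    """Timestamps are not strictly increasing."""


class AlignmentError(DriveStressError, ValueError):
    """Streams do not overlap long enough to analyse jointly."""


class EmptySliceError(DriveStressError, ValueError):
    """A requested time slice contains no samples."""


class SchemaError(DriveStressError, KeyError):
    """A feature required by a model is missing from the input."""


class DegenerateLabelsError(DriveStressError, ValueError):
    """A labeling or fit target contains a single class only."""


class SelectionError(DriveStressError, ValueError):
    """No threshold pair survives the selection constraints."""


class SeparationWarning(UserWarning):
    """Perfect separation detected while fitting a logistic model."""
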