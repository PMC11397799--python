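"""Exception hierarchy.

Every rejection of an input is a named error; nothing is silently dropped.
"""


class CanopySpecError(Exception):
    """Base class for all canopyspec errors."""


class ManifestFormatError(CanopySpecError):
    """Manifest file is structurally malformed (missing columns, unreadable)."""


class ManifestValidationError(CanopySpecError):
    """Manifest contents violate a constraint (duplicate triple, bad label, missing file)."""


class StackError(CanopySpecError):
    """Channels of one stack are mutually inconsistent (e.g. dimension mismatch)."""


class ChannelError(CanopySpecError):
    """A single channel image is unusable (e.g. RGB where grayscale expected)."""


class MissingChannelError(CanopySpecError):
    """An operation needs a channel the stack does not carry."""


class DegenerateImageError(CanopySpecError):
    """Image has no usable signal (zero variance) for registration."""


class InsufficientSignalError(CanopySpecError):
    """Too few confident tile matches to fit an affine transform."""


class DegenerateHistogramError(CanopySpecError):
    """Automatic thresholding on a constant image is undefined."""


class RankDeficiencyError(CanopySpecError):
    """Too few distinct treatment levels to identify a quadratic."""


class InsufficientDataError(CanopySpecError):
    """Not enough observations for the requested fit."""


class ParameterError(CanopySpecError):
    """An operation parameter is out of its valid domain."""


class SceneSpecError(CanopySpecError):
    """A synthetic scene specification is incomplete or inconsistent."""
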