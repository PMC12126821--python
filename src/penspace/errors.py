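"""Exception hierarchy for penspace.

Every error raised by the library derives from :class:`PenspaceError` so the
CLI can map any pipeline failure to a nonzero exit with the module's message.
"""


class PenspaceError(Exception):
    """Base class for all penspace errors."""


class ConfigurationError(PenspaceError):
    """Invalid parameter value or combination (unknown algorithm, even kernel...)."""


class ShapeMismatchError(PenspaceError):
    """Two arrays that must share dimensions do not."""


class EmptyInputError(PenspaceError):
    """An operation received zero frames / zero masks / an all-zero region."""


class DecodeError(PenspaceError):
    """A video container or image file could not be decoded."""


class BoundsError(PenspaceError):
    """A scripted blob leaves the frame bounds."""


class AlignmentError(PenspaceError):
    """Parallel sequences (frames vs per-frame maps) differ in length."""


class DegenerateTrackError(PenspaceError):
    """Fewer than two distinct centroid positions: KDE ranges are undefined."""
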