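"""Exception hierarchy."""


class GCCMError(Exception):
    """Base class for all errors raised by this package."""


class SupportMismatchError(GCCMError):
    """The two fields do not live on the same spatial support."""


class LibraryTooSmallError(GCCMError):
    """A library does not contain enough valid states for neighbor search."""


class UndefinedSkillError(GCCMError):
    """Prediction skill is undefined (zero variance or too few predictions)."""


class InvalidAdjacencyError(GCCMError):
    """Polygon adjacency is asymmetric or contains self-loops."""
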