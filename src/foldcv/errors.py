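"""Exception types raised across foldcv."""


class FoldcvError(Exception):
    """Base class for all foldcv errors."""


class StructureError(FoldcvError):
    """Malformed or unusable structure input."""


class UndefinedAngleError(FoldcvError):
    """A required backbone dihedral is undefined (terminus or chain break)."""


class SegmentError(FoldcvError):
    """A segment cannot be resolved or evaluated on the given profile."""


class LabelError(FoldcvError):
    """Malformed secondary-structure label input."""


class GridError(FoldcvError):
    """Ill-posed free-energy grid or path query."""
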