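"""Exception hierarchy.

Every error raised by the library derives from :class:`VelostreamError`
so callers (and the CLI) can catch one type at a stage boundary.
"""


class VelostreamError(Exception):
    """Base class for all velostream errors."""


class KeyLookupError(VelostreamError, KeyError):
    """A named key (obsm slot, cell id, feature id, modality) was not found."""

    def __init__(self, key: str, available, what: str = "key"):
        self.key = key
        self.available = sorted(map(str, available))
        msg = f"unknown {what} {key!r}; available: {', '.join(self.available) or '(none)'}"
        Exception.__init__(self, msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the full message
        return self.args[0]


class DimensionalityError(VelostreamError):
    """An embedding or velocity array has fewer than 3 components."""


class AlignmentError(VelostreamError):
    """Modalities of a multimodal container disagree on the cell set."""


class TableParseError(VelostreamError):
    """A delimited text table contains an unparseable value."""


class ParameterError(VelostreamError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class MissingVelocityError(VelostreamError):
    """An operation requiring per-cell velocities got a dataset without them."""


class MissingCloneError(VelostreamError):
    """An operation requiring clone labels got a dataset without them."""


class EmptyNeighborhoodError(VelostreamError):
    """No cells fall inside the trajectory neighborhood; suggest a larger radius."""


class EmptySelectionError(VelostreamError):
    """A spatial or clonal selection matched no cells."""
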