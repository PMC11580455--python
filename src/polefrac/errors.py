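"""Exception hierarchy for the polefrac pipeline.

All pipeline errors derive from :class:`PolefracError` so callers can catch
one base class; per-cell failures carry the cell label so batch drivers can
exclude the cell and continue.
"""


class PolefracError(Exception):
    """Base class for all polefrac errors."""


class ValidationError(PolefracError, ValueError):
    """A parameter or input value violates a documented precondition."""


class FormatError(PolefracError):
    """An input file is not in the expected raster/table format."""


class GeometryError(PolefracError):
    """A cell's shape does not admit a rod-cell medial axis.

    Raised for cells that are too small, round (axis shorter than twice the
    width), or split into multiple connected components.
    """

    def __init__(self, message: str, label: int | None = None):
        super().__init__(message)
        self.label = label


class QuantificationError(PolefracError):
    """A cell cannot be quantified (e.g. non-positive total fluorescence)."""

    def __init__(self, message: str, label: int | None = None):
        super().__init__(message)
        self.label = label


class PlacementError(PolefracError):
    """Cell placement failed after bounded retries.

    ``placed`` records how many cells were successfully placed before the
    generator gave up, so callers can retry with a larger field of view or
    fewer cells.
    """

    def __init__(self, message: str, placed: int):
        super().__init__(message)
        self.placed = placed


class DegenerateDataError(PolefracError):
    """A statistic is undefined for the given data (e.g. zero pooled variance
    with unequal means)."""
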