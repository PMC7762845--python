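"""Named failure modes raised across the toolkit.

Every error that a caller might plausibly want to catch has its own class;
generic ``ValueError``/``TypeError`` are reserved for programming mistakes.
"""


class NeoqcError(Exception):
    """Base class for all toolkit-specific failures."""


class FileFormatError(NeoqcError):
    """A file exists but is not in the expected on-disk format."""


class MissingFileError(NeoqcError, FileNotFoundError):
    """A required input path does not exist."""


class GridMismatchError(NeoqcError):
    """Two images that must share a voxel grid do not.

    Nothing in the toolkit resamples; paired images must already live on
    the same grid, so a mismatch is always an error, never broadcast.
    """


class DegenerateInputError(NeoqcError):
    """Input is structurally valid but degenerate for the requested metric
    (constant image for NMI, empty mask, fewer than 2 slices/frames...)."""


class DesignMatrixError(NeoqcError):
    """A regression design is empty, rank-deficient or inconsistent."""
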