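"""Exception hierarchy for cdsk.

All package-specific failures derive from :class:`CDSKError` so callers
(and the CLI, which maps them to exit code 2) can catch one base class.
"""


class CDSKError(Exception):
    """Base class for all cdsk errors."""


class InputFormatError(CDSKError):
    """Malformed or unsupported input data (bad pitch, ragged columns, ...)."""


class InsufficientDataError(InputFormatError):
    """Too few data points to proceed."""


class ParseError(InputFormatError):
    """A non-numeric cell inside a numeric data block; names the line."""


class NormalizationError(CDSKError):
    """Missing or invalid normalization metadata (concentration, pathlength, ...)."""


class CoverageError(CDSKError):
    """Requested wavelength/temperature range not covered by the data."""


class UpsamplingError(CDSKError):
    """Requested grid pitch finer than the native pitch of the data."""


class DataError(CDSKError):
    """Non-finite or otherwise unusable values inside the analysis range."""


class ContentError(CDSKError):
    """A structurally valid file with no usable content (e.g. no protein chain)."""


class AlphabetError(CDSKError):
    """Sequence letters outside the accepted amino-acid alphabet."""

    def __init__(self, letters, positions):
        self.letters = letters
        self.positions = positions
        super().__init__(
            f"unknown sequence letter(s) {sorted(set(letters))} at position(s) {positions}"
        )


class ConvergenceWarningError(CDSKError):
    """Fit finished without meeting convergence criteria (CLI exit code 3)."""
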