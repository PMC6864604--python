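"""Exception hierarchy for the LFA readout pipeline."""


class LFAQuantError(Exception):
    """Base class for all lfaquant errors."""


class UnsupportedFormatError(LFAQuantError):
    """Raised for image files that are not 8-bit-per-channel rasters."""


class GeometryError(LFAQuantError):
    """Raised when a region or band does not fit the required geometry."""


class DegenerateInputError(LFAQuantError):
    """Raised when an input has no information to act on (e.g. constant values)."""


class InvalidStripError(LFAQuantError):
    """Raised when the control line is absent: the assay did not run."""


class CalibrationRangeError(LFAQuantError):
    """Raised when a requested target lies outside the achievable response range."""
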