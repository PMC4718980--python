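"""Exception hierarchy.

Everything derives from :class:`ModspecError` (a ``ValueError``) so callers can
catch the package's failures with a single except clause while still getting
sensible behaviour from code that only knows about ``ValueError``.
"""


class ModspecError(ValueError):
    """Base class for all errors raised by this package."""


class ChannelError(ModspecError):
    """Audio file is not mono."""


class FormatError(ModspecError):
    """Audio file is unreadable, empty, or not PCM WAV."""


class DegenerateSignalError(ModspecError):
    """Signal is identically zero where a nonzero signal is required."""


class DegenerateSpectrumError(ModspecError):
    """Spectrum is constant/zero where variation is required (e.g. RALA)."""


class DegenerateFeatureError(ModspecError):
    """A feature column has zero variance / is constant."""


class TooShortError(ModspecError):
    """Signal or frame shorter than the analysis window requires."""


class EmptySelectionError(ModspecError):
    """A frequency restriction selected no band centers."""


class SizeError(ModspecError):
    """Input too small (matrix smaller than mask, empty result, ...)."""


class ClassError(ModspecError):
    """Both classes are required but only one is present."""


class GridError(ModspecError):
    """Tuning grids do not match where they must."""


class ParameterError(ModspecError):
    """Synthesis or configuration parameters violate their invariants."""


class AliasingError(ParameterError):
    """Requested tone frequency at or above the Nyquist frequency."""
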