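"""Exception hierarchy.

Each error class maps to a distinct command-line exit code (see
:mod:`spectraplex.cli`), so pipeline failures are machine-distinguishable.
"""


class SpectraplexError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(SpectraplexError):
    """Invalid or unknown assay / channel / stain configuration."""

    exit_code = 2


class MissingInputError(SpectraplexError):
    """A required input file or field (e.g. a blank reference) is absent."""

    exit_code = 3


class ChannelMismatchError(SpectraplexError):
    """Channel orders or channel sets of two objects do not agree."""

    exit_code = 4


class CalibrationError(SpectraplexError):
    """Single-stain calibration failed (empty mask, missing blank, ...)."""

    exit_code = 5


class DegenerateChannelError(SpectraplexError):
    """An illumination band falls entirely outside the camera sensitivity."""

    exit_code = 6


class GenerationError(SpectraplexError):
    """The virtual-slide generator could not satisfy its constraints."""

    exit_code = 7
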