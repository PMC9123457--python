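"""Exception hierarchy with stable exit codes for the command line.

Each error family maps to a distinct nonzero process exit code so shell
pipelines can distinguish an unreadable file from, say, a localization
failure.
"""


class DuobeamError(Exception):
    """Base class for all duobeam errors."""

    exit_code = 1


class ImageIOError(DuobeamError):
    """File missing, unreadable, or not a decodable image."""

    exit_code = 10


class ImageFormatError(DuobeamError):
    """Decodable image with an unusable layout (wrong channel count, too small)."""

    exit_code = 11


class OrientationError(DuobeamError):
    """Neither vertical orientation shows red-channel dominance at one end."""

    exit_code = 20


class LocalizationError(DuobeamError):
    """Spectral stripes could not be located unambiguously."""

    exit_code = 21


class WavelengthError(DuobeamError):
    """Degenerate or inconsistent pixel-to-wavelength anchors."""

    exit_code = 22


class PhotometryError(DuobeamError):
    """Invalid intensities or band outside the representable wavelength span."""

    exit_code = 30


class CalibrationError(DuobeamError):
    """Insufficient or degenerate calibration data, or a corrupt calibration file."""

    exit_code = 40
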