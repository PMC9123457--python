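"""End-to-end analysis: photograph in, absorbance (and concentration) out.

Stages, in order: canonical orientation (red at top), stripe localization
via the vibrancy map, per-stripe intensity profiles, wavelength calibration
from the reference spectrum's red and blue channel peaks, band intensity at
the target wavelength, dual-beam absorbance, blank subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DuobeamError
from .imaging import RgbImage, validate_orientation
from .localization import locate_spectra
from .photometry import AbsorbanceResult, absorbance, band_intensity, prominent_channel
from .wavecal import build_wavelength_map, extract_profile, find_channel_peak

__all__ = ["RunConfig", "PRESET_WAVELENGTHS_NM", "analyze", "blank_offset"]

log = logging.getLogger(__name__)

#: Target wavelengths of the supported colorimetric assays (nm):
#: acid-reduction nitrate assay, ferrozine iron(II), methylene-blue sulfide.
PRESET_WAVELENGTHS_NM = {"nitrate": 535.0, "ferrozine": 550.0, "sulfide": 660.0}


@dataclass
class RunConfig:
    """Analysis parameters.

    The LED anchor wavelengths are device-specific: they are the true
    wavelengths of the red- and blue-channel peaks of this LED as measured
    once with a bench spectrometer. The defaults are plausible for a generic
    phosphor white LED and must be overridden for a real device.
    """

    target_wavelength_nm: float = 535.0
    halfwidth_nm: float = 5.0
    lambda_red_nm: float = 600.0
    lambda_blue_nm: float = 452.0
    smooth_halfwidth_rows: int = 2
    channel_policy: str = "prominent"  # or "sum"
    exponent: float = 1.0  # sensor power-law n; 1.0 = no correction
    threshold_fraction: float = 0.20
    bridge_gap_px: int = 2
    max_tilt_deg: float = 2.5

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        try:
            wl = PRESET_WAVELENGTHS_NM[name]
        except KeyError:
            raise DuobeamError(
                f"unknown preset {name!r}; available: "
                f"{', '.join(sorted(PRESET_WAVELENGTHS_NM))}"
            ) from None
        return cls(target_wavelength_nm=wl, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


def _as_image(img) -> RgbImage:
    if isinstance(img, RgbImage):
        return img
    return RgbImage(np.asarray(img, dtype=np.float64))


def analyze(img, config: RunConfig, blank: float = 0.0) -> AbsorbanceResult:
    """Measure blank-corrected absorbance at the configured target wavelength.

    ``blank`` is the per-wavelength offset previously measured on a
    two-empty-cuvettes frame (0.0 when no blank has been taken).
    """
    image = validate_orientation(_as_image(img))
    ref_region, samp_region = locate_spectra(
        image,
        fraction=config.threshold_fraction,
        bridge_gap=config.bridge_gap_px,
        max_tilt_deg=config.max_tilt_deg,
    )
    ref = extract_profile(image, ref_region)
    samp = extract_profile(image, samp_region)

    row_red = find_channel_peak(ref, "R", config.smooth_halfwidth_rows)
    row_blue = find_channel_peak(ref, "B", config.smooth_halfwidth_rows)
    wmap = build_wavelength_map(
        row_red, row_blue, config.lambda_red_nm, config.lambda_blue_nm
    )

    if config.channel_policy == "prominent":
        channel = prominent_channel(
            ref, wmap, config.target_wavelength_nm, config.halfwidth_nm
        )
    elif config.channel_policy == "sum":
        channel = "sum"
    else:
        raise DuobeamError(
            f"unknown channel policy {config.channel_policy!r}; "
            "use 'prominent' or 'sum'"
        )
    I_ref = band_intensity(
        ref, wmap, config.target_wavelength_nm, config.halfwidth_nm, channel
    )
    I_samp = band_intensity(
        samp, wmap, config.target_wavelength_nm, config.halfwidth_nm, channel
    )
    A_raw = absorbance(I_samp, I_ref)
    log.debug(
        "lambda=%.1f nm channel=%s I_ref=%.4f I_samp=%.4f A_raw=%.4f",
        config.target_wavelength_nm, channel, I_ref, I_samp, A_raw,
    )
    return AbsorbanceResult(
        wavelength_nm=config.target_wavelength_nm,
        A_raw=A_raw,
        A_blank=blank,
        n_exponent=config.exponent,
        channel=channel,
    )


def absorbance_spectrum(img, config: RunConfig, blank: float = 0.0):
    """Per-row absorbance over the rows both stripes share.

    Returns ``(wavelengths_nm, A)`` arrays using the prominent channel of
    the reference spectrum; rows where either beam is too dark for a stable
    ratio (below 2% full scale) are dropped.
    """
    image = validate_orientation(_as_image(img))
    ref_region, samp_region = locate_spectra(
        image,
        fraction=config.threshold_fraction,
        bridge_gap=config.bridge_gap_px,
        max_tilt_deg=config.max_tilt_deg,
    )
    ref = extract_profile(image, ref_region)
    samp = extract_profile(image, samp_region)
    row_red = find_channel_peak(ref, "R", config.smooth_halfwidth_rows)
    row_blue = find_channel_peak(ref, "B", config.smooth_halfwidth_rows)
    wmap = build_wavelength_map(
        row_red, row_blue, config.lambda_red_nm, config.lambda_blue_nm
    )
    channel = prominent_channel(
        ref, wmap, config.target_wavelength_nm, config.halfwidth_nm
    )
    common = np.intersect1d(ref.rows, samp.rows)
    i_ref = ref.channel(channel)[np.searchsorted(ref.rows, common)]
    i_samp = samp.channel(channel)[np.searchsorted(samp.rows, common)]
    keep = (i_ref > 0.02) & (i_samp > 0.02)
    lam = wmap.row_to_wavelength(common[keep])
    A = -np.log(i_samp[keep] / i_ref[keep]) - blank
    return lam, A


def blank_offset(blank_img, config: RunConfig) -> float:
    """Absorbance offset of a blank frame (two empty cuvettes).

    The left-right beam intensity ratio is constant over a session, so this
    offset, subtracted from subsequent raw absorbances, cancels beam and
    sensor asymmetry.
    """
    try:
        return analyze(blank_img, config, blank=0.0).A_raw
    except DuobeamError as exc:
        raise type(exc)(f"blank measurement failed: {exc}") from exc
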