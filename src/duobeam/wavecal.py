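"""Pixel-to-wavelength calibration from the two LED anchor peaks.

The white LED behind the cuvettes has a narrow blue emission peak and a
broad phosphor peak whose red-channel response peaks at a longer
wavelength. Both show up as channel maxima in the reference spectrum, and
their true wavelengths are measured once per LED type with a bench
spectrometer. Two anchors determine an affine row-to-nanometer map, which
is exact for first-order grating dispersion at small angles and treated as
an approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import PhotometryError, WavelengthError
from .localization import SpectrumRegion

__all__ = [
    "IntensityProfile",
    "WavelengthMap",
    "extract_profile",
    "find_channel_peak",
    "build_wavelength_map",
]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass(frozen=True)
class IntensityProfile:
    """Per-row channel means across one stripe's width.

    ``rows`` holds global image row indices so profiles from both stripes
    share the spectral axis; ``channels`` is (n_rows, 3) in [0, 1].
    """

    rows: np.ndarray
    channels: np.ndarray

    def __post_init__(self) -> None:
        if self.rows.shape[0] != self.channels.shape[0]:
            raise ValueError("rows and channels lengths differ")

    def __len__(self) -> int:
        return self.rows.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[:, _CHANNEL_INDEX[name]]


@dataclass(frozen=True)
class WavelengthMap:
    """Affine map between image row and wavelength, anchored at two peaks.

    Red anchor sits above the blue one (smaller row index) because the frame
    is oriented red-at-top; wavelength therefore decreases with row index.
    """

    row_red: float
    lambda_red: float
    row_blue: float
    lambda_blue: float

    @property
    def nm_per_row(self) -> float:
        """Signed dispersion; negative because wavelength falls going down."""
        return (self.lambda_blue - self.lambda_red) / (self.row_blue - self.row_red)

    def row_to_wavelength(self, row):
        return self.lambda_red + self.nm_per_row * (np.asarray(row, float) - self.row_red)

    def wavelength_to_row(self, wavelength):
        return self.row_red + (np.asarray(wavelength, float) - self.lambda_red) / self.nm_per_row


def extract_profile(img, region: SpectrumRegion) -> IntensityProfile:
    """Average each channel across the stripe's columns, row by row."""
    data = np.asarray(getattr(img, "data", img), dtype=np.float64)
    h, w = data.shape[:2]
    if not (0 <= region.row_start < region.row_end <= h
            and 0 <= region.col_start < region.col_end <= w):
        raise ValueError(f"region {region} outside image bounds {h}x{w}")
    block = data[region.row_start : region.row_end,
                 region.col_start : region.col_end]
    return IntensityProfile(
        rows=np.arange(region.row_start, region.row_end),
        channels=block.mean(axis=1),
    )


def find_channel_peak(
    profile: IntensityProfile, channel: str, smooth_halfwidth: int = 2
) -> int:
    """Global row index of a channel's maximum after moving-average smoothing.

    Raw argmax is fragile to single-pixel noise, so the channel is smoothed
    with a (2*halfwidth + 1)-row moving average first (default: 5 rows).
    Ties break toward the smaller row index.
    """
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"channel must be one of R, G, B; got {channel!r}")
    values = profile.channel(channel)
    if len(profile) <= 2 * smooth_halfwidth + 1:
        raise ValueError(
            f"profile of {len(profile)} rows too short for "
            f"smoothing half-width {smooth_halfwidth}"
        )
    if not np.any(values > 0):
        raise WavelengthError(f"peak not found: channel {channel} is entirely zero")
    if smooth_halfwidth > 0:
        values = uniform_filter1d(values, 2 * smooth_halfwidth + 1, mode="nearest")
    return int(profile.rows[int(np.argmax(values))])


def build_wavelength_map(
    row_red: float, row_blue: float, lambda_red: float, lambda_blue: float
) -> WavelengthMap:
    """Affine wavelength map through the red and blue anchor points."""
    if row_red == row_blue or lambda_red == lambda_blue:
        raise WavelengthError(
            f"degenerate anchors: rows ({row_red}, {row_blue}), "
            f"wavelengths ({lambda_red}, {lambda_blue}) nm"
        )
    if lambda_red <= lambda_blue:
        raise WavelengthError(
            f"red anchor wavelength {lambda_red} nm must exceed blue "
            f"{lambda_blue} nm"
        )
    if row_red >= row_blue:
        raise WavelengthError(
            f"red anchor row {row_red} must sit above blue row {row_blue} "
            "(is the image oriented red-at-top?)"
        )
    return WavelengthMap(row_red, lambda_red, row_blue, lambda_blue)


def band_rows(
    profile: IntensityProfile, wmap: WavelengthMap, lambda0: float, halfwidth: float
) -> np.ndarray:
    """Indices into ``profile`` whose wavelength lies within lambda0 +/- halfwidth."""
    lam = wmap.row_to_wavelength(profile.rows)
    span = (lam.min(), lam.max())
    if lambda0 - halfwidth < span[0] or lambda0 + halfwidth > span[1]:
        raise PhotometryError(
            f"band {lambda0}+/-{halfwidth} nm outside the stripe's span "
            f"{span[0]:.1f}-{span[1]:.1f} nm"
        )
    idx = np.flatnonzero(np.abs(lam - lambda0) <= halfwidth)
    if idx.size == 0:
        raise PhotometryError(
            f"band {lambda0}+/-{halfwidth} nm narrower than one pixel row "
            f"({abs(wmap.nm_per_row):.2f} nm/row)"
        )
    return idx
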