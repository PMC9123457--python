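"""Dual-beam absorbance at a target wavelength.

Both beams are captured in one frame, so the absorbance
``A = -ln(I_sample / I_reference)`` cancels lighting and sensor variation
shared by the two paths. A blank frame (two empty cuvettes) measured at the
start of a session zeroes out the residual left-right beam asymmetry, which
is a constant intensity ratio and hence an additive offset in absorbance.
Camera pixel values follow a power law P ~ I^n of the incident intensity,
which compresses measured absorbances by the factor n; ``correct_exponent``
undoes it and ``estimate_exponent`` fits n from known intensity steps.

The natural-log convention is canonical here; ``to_decadic`` converts to
the base-10 absorbance commercial instruments report.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import PhotometryError
from .wavecal import IntensityProfile, WavelengthMap, band_rows

__all__ = [
    "AbsorbanceResult",
    "band_intensity",
    "prominent_channel",
    "absorbance",
    "to_decadic",
    "correct_exponent",
    "estimate_exponent",
    "BlankStore",
]

SATURATION_LEVEL = 0.995


@dataclass(frozen=True)
class AbsorbanceResult:
    """Blank-corrected absorbance at one wavelength.

    ``A = A_raw - A_blank`` by definition; ``A_linear`` additionally divides
    by the sensor exponent ``n_exponent`` (1.0 means no correction) to undo
    the camera's power-law compression.
    """

    wavelength_nm: float
    A_raw: float
    A_blank: float
    n_exponent: float
    channel: str

    @property
    def A(self) -> float:
        return self.A_raw - self.A_blank

    @property
    def A_linear(self) -> float:
        return correct_exponent(self.A, self.n_exponent)


def prominent_channel(
    reference: IntensityProfile,
    wmap: WavelengthMap,
    lambda0: float,
    halfwidth: float,
) -> str:
    """Channel with the largest band mean in the *reference* profile.

    Decided on the reference beam so the choice cannot depend on how much
    the sample absorbs.
    """
    idx = band_rows(reference, wmap, lambda0, halfwidth)
    means = reference.channels[idx].mean(axis=0)
    return "RGB"[int(np.argmax(means))]


def band_intensity(
    profile: IntensityProfile,
    wmap: WavelengthMap,
    lambda0: float,
    halfwidth: float = 5.0,
    channel: str = "sum",
) -> float:
    """Mean intensity over the rows within ``lambda0 +/- halfwidth`` nm.

    ``channel`` is "R", "G", "B", or "sum" (the three channels added).
    A mean (not a sum) over rows is used so changing the half-width does not
    rescale the result. Values at or above the saturation level trigger a
    warning: intensity ratios are unreliable once the sensor clips.
    """
    idx = band_rows(profile, wmap, lambda0, halfwidth)
    block = profile.channels[idx]
    if np.any(block >= SATURATION_LEVEL):
        warnings.warn(
            f"band at {lambda0} nm contains saturated pixels (>= "
            f"{SATURATION_LEVEL}); absorbance may be unreliable",
            stacklevel=2,
        )
    if channel == "sum":
        return float(block.sum(axis=1).mean())
    return float(profile.channel(channel)[idx].mean())


def absorbance(I: float, I0: float) -> float:
    """Natural-log absorbance -ln(I / I0).

    Negative results (sample brighter than reference) are passed through
    unclamped; they carry real information about beam imbalance.
    """
    if I <= 0 or I0 <= 0:
        raise PhotometryError(
            f"nonpositive intensity (I={I!r}, I0={I0!r}); check for "
            "saturation or underexposure"
        )
    return -math.log(I / I0)


def to_decadic(A: float) -> float:
    """Convert natural-log absorbance to the decadic convention A10 = A / ln 10."""
    return A / math.log(10.0)


def correct_exponent(A_measured: float, n: float) -> float:
    """Undo the sensor power law: the slope compression divides out as A / n."""
    if n <= 0:
        raise PhotometryError(f"sensor exponent must be positive, got {n}")
    return A_measured / n


def estimate_exponent(pairs) -> float:
    """Fit the sensor exponent n of P ~ I^n from (intensity, pixel value) pairs.

    Least-squares slope of ln(pixel value) on ln(relative intensity);
    requires at least three strictly positive pairs with unequal intensities.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise PhotometryError("need at least 3 (intensity, pixel value) pairs")
    I, P = arr[:, 0], arr[:, 1]
    if np.any(I <= 0) or np.any(P <= 0):
        raise PhotometryError("intensities and pixel values must be positive")
    if np.allclose(I, I[0]):
        raise PhotometryError("intensities are all equal; exponent unidentifiable")
    result = stats.linregress(np.log(I), np.log(P))
    return float(result.slope)


class BlankStore:
    """Per-wavelength blank offsets persisted as a small JSON sidecar.

    The blank step must be repeated at the start of each measurement series;
    the store simply carries those offsets between process invocations.
    """

    def __init__(self, offsets: dict[float, float] | None = None):
        self._offsets: dict[float, float] = dict(offsets or {})

    @staticmethod
    def _key(wavelength_nm: float) -> float:
        return round(float(wavelength_nm), 2)

    def set(self, wavelength_nm: float, offset: float) -> None:
        self._offsets[self._key(wavelength_nm)] = float(offset)

    def get(self, wavelength_nm: float, default: float | None = None) -> float | None:
        return self._offsets.get(self._key(wavelength_nm), default)

    def __len__(self) -> int:
        return len(self._offsets)

    def save(self, path: str | Path) -> None:
        payload = {f"{k:g}": v for k, v in sorted(self._offsets.items())}
        Path(path).write_text(json.dumps({"blank_offsets_nm": payload}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BlankStore":
        payload = json.loads(Path(path).read_text())
        return cls({float(k): float(v) for k, v in payload["blank_offsets_nm"].items()})
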