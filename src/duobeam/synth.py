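"""Forward model of the dual-beam instrument.

Renders the photograph the analysis pipeline expects — two near-vertical
diffraction stripes of a white LED over a dark field — with every physical
parameter known, so each analysis stage can be tested against ground truth
without hardware.

The model chain per stripe pixel: the pixel's row maps linearly to a
wavelength (first-order grating dispersion); the LED emission (narrow blue
peak plus broad phosphor peak, both Gaussian) is attenuated by Beer-Lambert
absorption ``exp(-eps(lambda) * c * l)`` in the sample beam (and by a
left-right beam-imbalance factor); the camera weighs the arriving light by
Gaussian per-channel spectral sensitivities, applies a power-law response
``P ~ I^n``, and adds Gaussian pixel noise, clipping to [0, 1]. A small
in-plane rotation emulates imperfect phone alignment.

Deliberately not modeled: Poisson shot noise, higher diffraction orders
(the hardware slit suppresses them), stray light, and turbidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import rotate as nd_rotate

__all__ = [
    "LedModel",
    "CameraModel",
    "SceneConfig",
    "GroundTruth",
    "emission",
    "sensitivity",
    "attenuation_coefficient",
    "transmit",
    "render",
    "render_flat",
    "make_series",
]


def _gaussian(x, center, width):
    return np.exp(-0.5 * ((np.asarray(x, float) - center) / width) ** 2)


@dataclass(frozen=True)
class LedModel:
    """White-LED emission: narrow blue die peak + broad phosphor peak (Gaussians)."""

    blue_center_nm: float = 450.0
    blue_width_nm: float = 15.0
    blue_amplitude: float = 1.0
    broad_center_nm: float = 560.0
    broad_width_nm: float = 60.0
    broad_amplitude: float = 0.9

    def __post_init__(self) -> None:
        if min(self.blue_amplitude, self.broad_amplitude) <= 0:
            raise ValueError("LED amplitudes must be positive")
        if min(self.blue_width_nm, self.broad_width_nm) <= 0:
            raise ValueError("LED peak widths must be positive")
        if self.blue_center_nm >= self.broad_center_nm:
            raise ValueError("blue peak must sit below the phosphor peak")


@dataclass(frozen=True)
class CameraModel:
    """Gaussian per-channel spectral sensitivities + power-law response.

    ``exponent`` is the n of P ~ I^n (1.0 = linear sensor); ``noise_sd`` is
    the additive per-pixel Gaussian noise applied after the power law.
    """

    r_center_nm: float = 610.0
    g_center_nm: float = 540.0
    b_center_nm: float = 465.0
    width_nm: float = 35.0
    exponent: float = 0.64
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("sensor exponent must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics, and chemistry of one rendered scene.

    The absorber is a Gaussian band: eps(lambda) peaks at
    ``absorber_center_nm`` with strength ``epsilon`` (absorbance per mg/L
    per cm), so the pre-sensor absorbance at band center is exactly
    ``epsilon * concentration * path_length_cm``.
    """

    height: int = 256
    width: int = 200
    ref_cols: Tuple[int, int] = (40, 80)
    sample_cols: Tuple[int, int] = (120, 160)
    row_span: Tuple[int, int] = (30, 226)
    lambda_top_nm: float = 680.0
    lambda_bottom_nm: float = 420.0
    rotation_deg: float = 0.0
    beam_imbalance: float = 1.0  # right/left incident intensity ratio
    exposure: float = 1.0
    peak_value: float = 0.70  # reference peak pixel value at exposure 1
    background: float = 0.05  # dark gray field (equal channels)
    path_length_cm: float = 1.0
    absorber_center_nm: float = 535.0
    absorber_width_nm: float = 40.0
    epsilon: float = 0.15  # absorbance per (mg/L) per cm at band center
    concentration: float = 0.0  # mg/L
    # optional third stripe: (col_start, col_end, fraction of peak vibrancy)
    extra_stripe: Optional[Tuple[int, int, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        r0, r1 = self.row_span
        if not (0 <= r0 < r1 <= self.height):
            raise ValueError(f"row span {self.row_span} outside frame height {self.height}")
        for c0, c1 in (self.ref_cols, self.sample_cols):
            if not (0 <= c0 < c1 <= self.width):
                raise ValueError(f"stripe columns ({c0}, {c1}) outside frame width {self.width}")
        if self.ref_cols[1] > self.sample_cols[0]:
            raise ValueError("reference and sample stripes must be disjoint in columns")
        if abs(self.rotation_deg) > 5.0:
            raise ValueError(
                f"rotation {self.rotation_deg} deg outside the renderer's "
                "validity range (+/-5 deg)"
            )
        if self.lambda_top_nm <= self.lambda_bottom_nm:
            raise ValueError("lambda_top_nm must exceed lambda_bottom_nm (red at top)")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")

    def row_wavelengths(self) -> np.ndarray:
        """Wavelength of each stripe row, top (red) to bottom (blue)."""
        r0, r1 = self.row_span
        return np.linspace(self.lambda_top_nm, self.lambda_bottom_nm, r1 - r0)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the renderer knows that the analysis must recover."""

    ref_mask: np.ndarray
    sample_mask: np.ndarray
    red_peak_row: int
    blue_peak_row: int
    lambda_red: float
    lambda_blue: float
    band_center_row: int
    absorbance_true: float  # eps * c * l at the absorber band center, pre-sensor
    nm_per_row: float
    exponent: float
    noiseless: np.ndarray = field(repr=False)


def emission(led: LedModel, lam) -> np.ndarray:
    """Relative LED spectral intensity at wavelength(s) ``lam`` (nm)."""
    return (
        led.blue_amplitude * _gaussian(lam, led.blue_center_nm, led.blue_width_nm)
        + led.broad_amplitude * _gaussian(lam, led.broad_center_nm, led.broad_width_nm)
    )


def sensitivity(camera: CameraModel, lam) -> np.ndarray:
    """Per-channel camera sensitivity at ``lam``; shape (..., 3)."""
    lam = np.asarray(lam, float)
    return np.stack(
        [
            _gaussian(lam, camera.r_center_nm, camera.width_nm),
            _gaussian(lam, camera.g_center_nm, camera.width_nm),
            _gaussian(lam, camera.b_center_nm, camera.width_nm),
        ],
        axis=-1,
    )


def attenuation_coefficient(scene: SceneConfig, lam) -> np.ndarray:
    """eps(lambda): Gaussian absorption band, peak value ``scene.epsilon``."""
    return scene.epsilon * _gaussian(lam, scene.absorber_center_nm, scene.absorber_width_nm)


def transmit(emitted, scene: SceneConfig, beam: str, lam=None) -> np.ndarray:
    """Apply Beer-Lambert attenuation (sample beam) or beam imbalance (sample side).

    The reference beam passes unchanged; the sample beam is scaled by the
    right/left imbalance factor and attenuated by
    ``exp(-eps(lambda) * c * l)``.
    """
    emitted = np.asarray(emitted, float)
    if beam == "reference":
        return emitted
    if beam != "sample":
        raise ValueError(f"beam must be 'reference' or 'sample', got {beam!r}")
    if lam is None:
        raise ValueError("sample-beam transmission needs the wavelength(s)")
    eps = attenuation_coefficient(scene, lam)
    T = np.exp(-eps * scene.concentration * scene.path_length_cm)
    return emitted * scene.beam_imbalance * T


def _stripe_rows_post(scene: SceneConfig, led: LedModel, camera: CameraModel):
    """Noiseless post-gamma row colors for both stripes; shape (n_rows, 3) each."""
    lam = scene.row_wavelengths()
    sens = sensitivity(camera, lam)  # (n, 3)
    emitted = emission(led, lam)  # (n,)
    raw_ref = sens * emitted[:, None]
    raw_samp = sens * transmit(emitted, scene, "sample", lam)[:, None]
    # exposure gain fixed by the reference peak so the frame is well exposed
    gain = scene.exposure * scene.peak_value ** (1.0 / camera.exponent) / raw_ref.max()
    post_ref = (gain * raw_ref) ** camera.exponent
    post_samp = (gain * raw_samp) ** camera.exponent
    return post_ref, post_samp


def render(
    scene: SceneConfig,
    led: LedModel | None = None,
    camera: CameraModel | None = None,
    seed: int | None = None,
):
    """Render one frame; returns ``(image, ground_truth)``.

    ``image`` is a float64 (H, W, 3) array in [0, 1] — pass it straight to
    the analysis pipeline or save it as 16-bit PNG. Identical
    (scene, led, camera, seed) always give bit-identical output.
    """
    led = led or LedModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(scene.seed if seed is None else seed)

    post_ref, post_samp = _stripe_rows_post(scene, led, camera)
    r0, r1 = scene.row_span
    h, w = scene.height, scene.width

    img = np.full((h, w, 3), scene.background, dtype=np.float64)
    img[r0:r1, scene.ref_cols[0] : scene.ref_cols[1]] = post_ref[:, None, :]
    img[r0:r1, scene.sample_cols[0] : scene.sample_cols[1]] = post_samp[:, None, :]
    if scene.extra_stripe is not None:
        c0, c1, frac = scene.extra_stripe
        # scaled post-gamma so `frac` is the stripe's fraction of peak vibrancy
        img[r0:r1, c0:c1] = frac * post_ref[:, None, :]

    ref_mask = np.zeros((h, w), dtype=bool)
    ref_mask[r0:r1, scene.ref_cols[0] : scene.ref_cols[1]] = True
    samp_mask = np.zeros((h, w), dtype=bool)
    samp_mask[r0:r1, scene.sample_cols[0] : scene.sample_cols[1]] = True

    if scene.rotation_deg != 0.0:
        img = np.stack(
            [
                nd_rotate(
                    img[:, :, ch],
                    scene.rotation_deg,
                    reshape=False,
                    order=0,
                    mode="constant",
                    cval=scene.background,
                )
                for ch in range(3)
            ],
            axis=-1,
        )
        ref_mask = nd_rotate(ref_mask, scene.rotation_deg, reshape=False, order=0)
        samp_mask = nd_rotate(samp_mask, scene.rotation_deg, reshape=False, order=0)

    noiseless = np.clip(img, 0.0, 1.0)
    if camera.noise_sd > 0:
        img = noiseless + rng.normal(0.0, camera.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
    else:
        img = noiseless.copy()

    lam = scene.row_wavelengths()
    red_idx = int(np.argmax(post_ref[:, 0]))
    blue_idx = int(np.argmax(post_ref[:, 2]))
    band_idx = int(np.argmin(np.abs(lam - scene.absorber_center_nm)))
    gt = GroundTruth(
        ref_mask=ref_mask,
        sample_mask=samp_mask,
        red_peak_row=r0 + red_idx,
        blue_peak_row=r0 + blue_idx,
        lambda_red=float(lam[red_idx]),
        lambda_blue=float(lam[blue_idx]),
        band_center_row=r0 + band_idx,
        absorbance_true=float(
            scene.epsilon * scene.concentration * scene.path_length_cm
        ),
        nm_per_row=float((scene.lambda_bottom_nm - scene.lambda_top_nm) / (len(lam) - 1)),
        exponent=camera.exponent,
        noiseless=noiseless,
    )
    return img, gt


def render_flat(scene: SceneConfig, level: float = 0.8) -> np.ndarray:
    """Degenerate scene: two uniform gray-white stripes, no spectral gradient.

    Useful for exercising the orientation-failure path — a colorless stripe
    gives the analysis nothing to orient by.
    """
    img = np.full((scene.height, scene.width, 3), scene.background, dtype=np.float64)
    r0, r1 = scene.row_span
    for c0, c1 in (scene.ref_cols, scene.sample_cols):
        img[r0:r1, c0:c1] = level
    return img


def make_series(
    scene: SceneConfig,
    concentrations: Sequence[float],
    replicates: int = 1,
    seed: int = 0,
    led: LedModel | None = None,
    camera: CameraModel | None = None,
) -> List[Tuple[np.ndarray, GroundTruth, float]]:
    """Render a calibration series: each concentration x replicate as one frame.

    Replicates at the same concentration differ only in their noise
    realization. Deterministic for a given seed.
    """
    concentrations = list(concentrations)
    if len(set(concentrations)) < 2:
        raise ValueError("need at least two distinct concentration levels")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be nonnegative")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(concentrations) * replicates
    ) % (2**31)
    out = []
    k = 0
    for c in concentrations:
        cfg = replace(scene, concentration=float(c))
        for _ in range(replicates):
            img, gt = render(cfg, led=led, camera=camera, seed=int(child_seeds[k]))
            out.append((img, gt, float(c)))
            k += 1
    return out
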