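"""Image loading and canonical orientation.

Every downstream stage consumes a single canonical representation: an
``RgbImage`` whose ``data`` array is float64 of shape (height, width, 3)
with all channels normalized to [0, 1]. Rows are the spectral axis with the
long-wavelength (red) end at row 0; columns are the spatial axis separating
the two stripes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v2 as iio
import numpy as np

from .errors import ImageFormatError, ImageIOError, OrientationError
from .localization import vibrancy_map

__all__ = ["RgbImage", "load_image", "validate_orientation", "MIN_DIMENSION"]

log = logging.getLogger(__name__)

#: Smallest workable frame edge; below this, peak localization at a few-nm
#: resolution is meaningless.
MIN_DIMENSION = 64


@dataclass(frozen=True)
class RgbImage:
    """An RGB frame with channels normalized to [0, 1].

    Attributes
    ----------
    data : numpy.ndarray
        Float array of shape (height, width, 3), every value in [0, 1].
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        d = self.data
        if d.ndim != 3 or d.shape[2] != 3:
            raise ImageFormatError(
                f"expected an (H, W, 3) array, got shape {d.shape}"
            )
        if d.shape[0] < MIN_DIMENSION or d.shape[1] < MIN_DIMENSION:
            raise ImageFormatError(
                f"frame {d.shape[0]}x{d.shape[1]} is below the minimum "
                f"workable size {MIN_DIMENSION}x{MIN_DIMENSION}"
            )
        if not np.isfinite(d).all():
            raise ImageFormatError("image contains non-finite values")
        if d.min() < 0.0 or d.max() > 1.0:
            raise ImageFormatError(
                f"channel values outside [0, 1]: range "
                f"[{d.min():.4g}, {d.max():.4g}]"
            )

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def flipped(self) -> "RgbImage":
        """The image mirrored along the spectral (row) axis."""
        return RgbImage(self.data[::-1].copy())


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise ImageFormatError(f"unsupported pixel dtype {arr.dtype}")


def load_image(path: str | Path) -> RgbImage:
    """Load a PNG/JPEG/TIFF file into the canonical float representation.

    8-bit sources are divided by 255, 16-bit by 65535. An alpha channel is
    dropped; grayscale input is rejected because the analysis needs per-channel
    color. JPEG EXIF orientation is applied by the decoder, since phone cameras
    routinely store rotated frames.
    """
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except FileNotFoundError as exc:
        raise ImageIOError(f"no such file: {path}") from exc
    except Exception as exc:  # decoder errors vary by plugin
        raise ImageIOError(f"cannot decode {path}: {exc}") from exc

    if arr.ndim == 2:
        raise ImageFormatError(
            f"{path}: single-channel (grayscale) image; 3 channels required"
        )
    if arr.ndim != 3:
        raise ImageFormatError(f"{path}: unexpected image shape {arr.shape}")
    n_ch = arr.shape[2]
    if n_ch < 3:
        raise ImageFormatError(
            f"{path}: {n_ch}-channel image; 3 channels required"
        )
    if n_ch > 4:
        raise ImageFormatError(
            f"{path}: {n_ch}-channel image; at most RGBA supported"
        )
    if n_ch == 4:
        arr = arr[:, :, :3]
    return RgbImage(np.clip(_normalize(arr), 0.0, 1.0))


def _red_dominance_scores(img: RgbImage) -> tuple[float, float] | None:
    """Mean (R - B) over high-vibrancy pixels in the top and bottom halves.

    Returns None when the image has no usable chromatic signal.
    """
    vmap = vibrancy_map(img)
    vmax = float(vmap.max())
    if vmax < 0.1:
        return None
    mask = vmap >= 0.2 * vmax
    rows = np.nonzero(mask.any(axis=1))[0]
    mid = (rows[0] + rows[-1] + 1) // 2
    diff = img.data[:, :, 0] - img.data[:, :, 2]
    top = mask.copy()
    top[mid:] = False
    bot = mask.copy()
    bot[:mid] = False
    if not top.any() or not bot.any():
        return None
    return float(diff[top].mean()), float(diff[bot].mean())


def validate_orientation(img: RgbImage) -> RgbImage:
    """Return the image with the red end of the spectra at row 0.

    The spectra must be photographed with the long-wavelength portion toward
    the top; if the frame arrives upside down it is flipped (and the flip is
    logged). If neither end of the stripes is red-dominant there is no
    spectral gradient to orient by and an :class:`OrientationError` is raised.
    """
    margin = 0.02  # minimum mean R-B excess to call an end "red"
    scores = _red_dominance_scores(img)
    if scores is None:
        raise OrientationError(
            "no chromatic signal: cannot establish spectral orientation"
        )
    top, bottom = scores
    if top > bottom and top > margin:
        return img
    if bottom > top and bottom > margin:
        log.info("spectra upside down; flipping along the spectral axis")
        return img.flipped()
    raise OrientationError(
        "neither end of the spectra is red-dominant "
        f"(top R-B {top:.3f}, bottom R-B {bottom:.3f})"
    )
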