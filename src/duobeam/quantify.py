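"""Beer-Lambert calibration curves and detection-limit statistics.

Absorbance is linear in concentration (A = eps*c*l), so a calibration is an
ordinary least-squares line through measured (concentration, absorbance)
standards; unknowns are read off by inverting it. Detection limits follow
the replicate convention: the limit of blank is mean(blank) + 3*SD(blank)
and the limit of detection adds 3*SD of low-concentration replicates on
top. The 3x multiplier corresponds to a ~99% one-sided confidence level and
is configurable; standard deviations use the sample (n-1) denominator, the
convention for replicate-based detection-limit work. Both limits live on
whatever scale the caller supplies (absorbance or concentration) — units
are carried, not assumed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError

__all__ = [
    "CalibrationCurve",
    "DetectionLimits",
    "fit_calibration",
    "predict_concentration",
    "limit_of_blank",
    "limit_of_detection",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line absorbance = slope * concentration + intercept for one assay."""

    slope: float
    intercept: float
    r_squared: float
    points: np.ndarray = field(repr=False)  # (n, 2) concentration, absorbance
    analyte: str = ""
    reagent: str = ""
    wavelength_nm: float = float("nan")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class DetectionLimits:
    """Limit of blank and limit of detection, on the scale of the inputs."""

    limit_of_blank: float
    limit_of_detection: float
    n_blank: int
    n_low: int


def fit_calibration(
    points: Sequence[Sequence[float]],
    analyte: str = "",
    reagent: str = "",
    wavelength_nm: float = float("nan"),
) -> CalibrationCurve:
    """Fit the OLS calibration line to (concentration, absorbance) standards.

    At least two points with distinct concentrations are required; a
    two-point fit passes through both exactly, so its R-squared is 1 by
    construction.
    """
    arr = np.asarray(points, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError(
            "insufficient calibration data: at least two "
            "(concentration, absorbance) points are required"
        )
    c, a = arr[:, 0], arr[:, 1]
    if np.ptp(c) == 0:
        raise CalibrationError(
            "calibration concentrations are all identical; slope unidentifiable"
        )
    res = stats.linregress(c, a)
    if arr.shape[0] == 2:
        r2 = 1.0
    else:
        # guard the degenerate flat-absorbance case where rvalue is nan
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        points=arr.copy(),
        analyte=analyte,
        reagent=reagent,
        wavelength_nm=float(wavelength_nm),
    )


def predict_concentration(curve: CalibrationCurve, A: float) -> float:
    """Invert the calibration line: c = (A - intercept) / slope.

    Negative predictions are returned as-is with a below-range warning, so
    the caller can decide whether to censor them.
    """
    if curve.slope == 0:
        raise CalibrationError("calibration slope is zero; cannot invert")
    c = (A - curve.intercept) / curve.slope
    if c < 0:
        warnings.warn(
            f"predicted concentration {c:.4g} is below the calibrated range",
            stacklevel=2,
        )
    return float(c)


def _sd(values: np.ndarray) -> float:
    return float(values.std(ddof=1))


def limit_of_blank(blank_values: Sequence[float], k: float = 3.0) -> float:
    """mean(blank) + k * SD(blank) over replicate blank measurements."""
    v = np.asarray(blank_values, dtype=np.float64)
    if v.size < 2:
        raise CalibrationError("insufficient replicates: need >= 2 blank values")
    return float(v.mean()) + k * _sd(v)


def limit_of_detection(
    lob: float,
    low_values: Sequence[float],
    k: float = 3.0,
    n_blank: int = 0,
) -> DetectionLimits:
    """LoD = LoB + k * SD of replicate low-concentration measurements."""
    if not np.isfinite(lob):
        raise CalibrationError(f"limit of blank must be finite, got {lob}")
    v = np.asarray(low_values, dtype=np.float64)
    if v.size < 2:
        raise CalibrationError("insufficient replicates: need >= 2 low-level values")
    return DetectionLimits(
        limit_of_blank=float(lob),
        limit_of_detection=float(lob) + k * _sd(v),
        n_blank=int(n_blank),
        n_low=int(v.size),
    )


_HEADER_PREFIX = "#"


def save_calibration(curve: CalibrationCurve, path: str | Path) -> None:
    """Write a curve as a human-readable CSV with a JSON header block."""
    meta = {
        "analyte": curve.analyte,
        "reagent": curve.reagent,
        "wavelength_nm": curve.wavelength_nm,
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "n_points": curve.n_points,
    }
    lines = [
        f"{_HEADER_PREFIX} duobeam calibration v1",
        f"{_HEADER_PREFIX} {json.dumps(meta)}",
        "concentration,absorbance",
    ]
    lines += [f"{float(c)!r},{float(a)!r}" for c, a in curve.points]
    Path(path).write_text("\n".join(lines) + "\n")


def load_calibration(path: str | Path) -> CalibrationCurve:
    """Read a calibration file and verify its stored fit by refitting.

    The stored slope/intercept/R-squared must agree with a fresh fit of the
    stored points to 1e-9 relative, guarding against hand-edited files.
    """
    path = Path(path)
    meta: dict = {}
    points: list[tuple[float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(_HEADER_PREFIX):
            body = line.lstrip(_HEADER_PREFIX).strip()
            if body.startswith("{"):
                try:
                    meta = json.loads(body)
                except json.JSONDecodeError as exc:
                    raise CalibrationError(
                        f"{path}:{lineno}: malformed JSON header: {exc}"
                    ) from exc
            continue
        if line.lower().replace(" ", "") == "concentration,absorbance":
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise CalibrationError(
                f"{path}:{lineno}: expected 'concentration,absorbance', got {raw!r}"
            )
        try:
            points.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise CalibrationError(f"{path}:{lineno}: non-numeric value: {raw!r}") from exc

    curve = fit_calibration(
        points,
        analyte=str(meta.get("analyte", "")),
        reagent=str(meta.get("reagent", "")),
        wavelength_nm=float(meta.get("wavelength_nm", float("nan"))),
    )
    for key, fresh in (
        ("slope", curve.slope),
        ("intercept", curve.intercept),
        ("r_squared", curve.r_squared),
    ):
        if key in meta:
            stored = float(meta[key])
            tol = 1e-9 * max(1.0, abs(stored))
            if abs(stored - fresh) > tol:
                raise CalibrationError(
                    f"{path}: stored {key} {stored!r} disagrees with refit "
                    f"{fresh!r}; file may be corrupt"
                )
    return curve
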