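"""Contact-free wound-area estimation from camera shooting height.

A flat reference shape ("prior graphic") of known physical area ``S_pi`` is
photographed at a ladder of nadir shooting heights; each height ``h`` yields
a pixel count ``λ``.  A least-squares fit of ``λ = f(h)`` then converts any
segmented wound's pixel count ``λ_w`` taken at an in-range height ``h_i``
into physical area:

    S_w = S_pi · λ_w / f(h_i)

Heights outside the calibrated range ``[h1, hn]`` are refused — the mapping
is an interpolation, never an extrapolation.  Heights are millimetres, areas
cm².  Wound pixels must be counted at the native capture resolution (the
probability map is resized back to the input image before thresholding), as
the ratio presumes prior and wound frames share one pixel grid.

Three calibration models are offered.  The default fits a polynomial in
powers of ``1/h`` (relative least squares, degree 4): a nadir pinhole camera
gives ``λ ∝ h⁻²`` exactly, so the inverse-height basis contains the true
curve, whereas a polynomial in raw ``h`` cannot track a 5:1 height range to
sub-percent accuracy.  A raw-height basis is still available
(``basis="height"``), as is the exact-physics mode ``λ = a/h²`` (a linear
fit against ``1/h²``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationRecord",
    "CalibrationCurve",
    "AreaEstimate",
    "HeightOutOfRange",
    "fit_calibration",
    "pixels_at_height",
    "estimate_area",
    "count_mask_pixels",
    "mbr_area",
    "relative_error",
    "read_calibration_csv",
    "write_calibration_csv",
]


class HeightOutOfRange(ValueError):
    """Requested shooting height lies outside the calibrated [h1, hn]."""


@dataclass(frozen=True)
class CalibrationRecord:
    h: float          # shooting height, mm
    lam: float        # prior-graphic pixel count at that height
    s_pi: float       # prior-graphic area, cm² (shared across the series)

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("shooting height must be positive")
        if self.lam <= 0:
            raise ValueError("pixel count must be positive")
        if self.s_pi <= 0:
            raise ValueError("prior area must be positive")


@dataclass
class CalibrationCurve:
    """Fitted λ = f(h) with its validity range and the prior area.

    ``coefficients`` are ascending powers of the scaled fit variable:
    ``h1/h`` for the inverse basis, ``h/h1`` for the height basis, and
    ``(1, 1/h²)`` for the exact-physics mode.
    """

    coefficients: np.ndarray
    h1: float
    hn: float
    s_pi: float
    model: str = "poly"           # "poly" or "inverse_square"
    basis: str = "inverse"        # "inverse" (powers of 1/h) or "height"
    residual_rms: float = 0.0
    max_rel_residual: float = 0.0

    def __call__(self, h: float) -> float:
        return pixels_at_height(self, h)

    def raw_coefficients(self) -> np.ndarray:
        """Coefficients in unscaled powers of the basis variable
        (h for basis="height", 1/h for basis="inverse")."""
        k = np.arange(len(self.coefficients))
        if self.basis == "height":
            return self.coefficients / self.h1**k
        return self.coefficients * self.h1**k


def fit_calibration(
    records: list[CalibrationRecord],
    degree: int = 4,
    model: str = "poly",
    basis: str = "inverse",
) -> CalibrationCurve:
    """Least-squares fit of prior-graphic pixel count against shooting height.

    The default inverse basis is fitted in relative least squares (residuals
    weighted by 1/λ), since λ spans a 25-fold range over 100–500 mm and the
    quantity that matters downstream is the relative error of λ_i.  Requires
    at least ``degree + 1`` distinct heights; the fitted curve must stay
    positive on a dense grid over [h1, hn].
    """
    if model not in ("poly", "inverse_square"):
        raise ValueError(f"unknown calibration model {model!r}")
    if basis not in ("inverse", "height"):
        raise ValueError(f"unknown basis {basis!r}")
    heights = np.array([r.h for r in records], dtype=np.float64)
    lams = np.array([r.lam for r in records], dtype=np.float64)
    s_pis = {r.s_pi for r in records}
    if len(s_pis) != 1:
        raise ValueError("all calibration records must share one prior area")
    n_distinct = len(np.unique(heights))
    n_coef = 2 if model == "inverse_square" else degree + 1
    if n_distinct < n_coef:
        raise ValueError(
            f"need at least {n_coef} distinct heights for this fit, got {n_distinct}"
        )
    order = np.argsort(heights)
    heights, lams = heights[order], lams[order]
    h1 = float(heights[0])
    if model == "inverse_square":
        # λ = c0 + c1 / h²  (c0 absorbs any constant offset; ideally ~0)
        design = np.c_[np.ones_like(heights), heights**-2.0]
        coef, *_ = np.linalg.lstsq(design, lams, rcond=None)
        fitted = design @ coef
    elif basis == "inverse":
        u = h1 / heights
        coef = np.polynomial.polynomial.polyfit(u, lams, degree, w=1.0 / lams)
        fitted = np.polynomial.polynomial.polyval(u, coef)
    else:
        u = heights / h1
        coef = np.polynomial.polynomial.polyfit(u, lams, degree)
        fitted = np.polynomial.polynomial.polyval(u, coef)
    resid = lams - fitted
    curve = CalibrationCurve(
        coefficients=np.asarray(coef),
        h1=h1,
        hn=float(heights[-1]),
        s_pi=s_pis.pop(),
        model=model,
        basis=basis,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        max_rel_residual=float(np.max(np.abs(resid) / lams)),
    )
    grid = np.linspace(curve.h1, curve.hn, 512)
    if np.any(_eval(curve, grid) <= 0):
        raise ValueError("fitted calibration curve is not positive over [h1, hn]")
    return curve


def _eval(curve: CalibrationCurve, h) -> np.ndarray:
    h = np.asarray(h, dtype=np.float64)
    if curve.model == "inverse_square":
        return curve.coefficients[0] + curve.coefficients[1] * h**-2.0
    u = curve.h1 / h if curve.basis == "inverse" else h / curve.h1
    return np.polynomial.polynomial.polyval(u, curve.coefficients)


def pixels_at_height(curve: CalibrationCurve, h_i: float) -> float:
    """Interpolated prior-graphic pixel count λ_i at height ``h_i`` (mm)."""
    if not (curve.h1 <= h_i <= curve.hn):
        raise HeightOutOfRange(
            f"height {h_i} mm outside calibrated range [{curve.h1}, {curve.hn}] mm"
        )
    lam = float(_eval(curve, h_i))
    if lam <= 0:
        raise ValueError("calibration curve evaluated non-positive")
    return lam


def count_mask_pixels(mask) -> int:
    """Exact wound pixel count λ_w of a binary mask at capture resolution."""
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("mask must be binary 0/1")
    return int(arr.sum())


@dataclass
class AreaEstimate:
    s_w_est: float                 # estimated wound area, cm²
    lambda_w: int
    lambda_i: float
    h_i: float
    s_pi: float
    s_w_real: float | None = None  # ground-truth-mask area, cm²
    s_w_mbr: float | None = None   # bounding-rectangle area, cm²
    error_pct: float | None = None

    def to_json(self) -> str:
        payload = {
            "S_wEst": self.s_w_est,
            "lambda_w": self.lambda_w,
            "lambda_i": self.lambda_i,
            "h_i": self.h_i,
            "S_pi": self.s_pi,
        }
        if self.s_w_real is not None:
            payload["S_wReal"] = self.s_w_real
        if self.s_w_mbr is not None:
            payload["S_wMbr"] = self.s_w_mbr
        if self.error_pct is not None:
            payload["E"] = self.error_pct
        return json.dumps(payload, indent=2)


def estimate_area(curve: CalibrationCurve, lambda_w: int, h_i: float) -> AreaEstimate:
    """Convert a wound pixel count into physical area:
    ``S_w = S_pi · λ_w / λ_i`` with ``λ_i = f(h_i)``."""
    if lambda_w < 0:
        raise ValueError("wound pixel count must be non-negative")
    lam_i = pixels_at_height(curve, h_i)
    s_w = curve.s_pi * lambda_w / lam_i
    return AreaEstimate(s_w_est=s_w, lambda_w=int(lambda_w), lambda_i=lam_i,
                        h_i=h_i, s_pi=curve.s_pi)


def mbr_area(mask, curve: CalibrationCurve, h_i: float, rotated: bool = False) -> float:
    """Area of the minimum bounding rectangle of the wound pixels, converted
    through the same calibration — the manual-measurement baseline.  Axis
    aligned by default; ``rotated=True`` uses the minimum rotated rectangle."""
    arr = np.asarray(mask)
    ys, xs = np.nonzero(arr)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding rectangle")
    if rotated:
        from shapely.geometry import MultiPoint

        hull = MultiPoint(list(zip(xs.tolist(), ys.tolist()))).convex_hull
        rect = hull.minimum_rotated_rectangle
        n_px = rect.area if rect.area > 0 else len(xs)
    else:
        n_px = (ys.max() - ys.min() + 1) * (xs.max() - xs.min() + 1)
    lam_i = pixels_at_height(curve, h_i)
    return float(curve.s_pi * n_px / lam_i)


def relative_error(s_true: float, s_hat: float) -> float:
    """Percentage error E = |s − ŝ| / s × 100."""
    if s_true <= 0:
        raise ValueError("true area must be positive")
    return abs(s_true - s_hat) / s_true * 100.0


# -- CSV interface -------------------------------------------------------------


def read_calibration_csv(path: str, s_pi: float) -> list[CalibrationRecord]:
    """Read a calibration table CSV with columns ``height_mm, pixel_count``."""
    df = pd.read_csv(path)
    required = {"height_mm", "pixel_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration CSV must have columns {sorted(required)}")
    return [
        CalibrationRecord(h=float(r.height_mm), lam=float(r.pixel_count), s_pi=s_pi)
        for r in df.itertuples()
    ]


def write_calibration_csv(records: list[CalibrationRecord], path: str) -> None:
    pd.DataFrame(
        {"height_mm": [r.h for r in records], "pixel_count": [r.lam for r in records]}
    ).to_csv(path, index=False)
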