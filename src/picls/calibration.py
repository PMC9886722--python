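"""Fluorescence-OD calibration on dilution series of PI-stained dead cells.

A serial dilution of stained dead cells (cuvette OD600 48 down to 0.05)
establishes (a) that PI fluorescence is linear in cell density, (b) the
affine map between plate-reader OD600 and cuvette OD600, and (c) the OD
window inside which that map holds: plate OD saturates above a knee
(cuvette OD ~12), so the top of the series is compressed and must be
trimmed before fitting.  ``detect_linear_range`` trims greedily from the
top of the series until the ordinary-least-squares fit of the remainder
reaches an R-squared threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, IncomparableError, NoLinearRangeError, NonInvertibleError

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "ODConversion",
    "PlateTypeComparison",
    "fit_line",
    "detect_linear_range",
    "convert_od",
    "compare_plate_types",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One dilution-series point: reference cuvette OD, plate OD, PI signal."""

    cuvette_od: float
    plate_od: float
    fluorescence: float

    def __post_init__(self):
        for name in ("cuvette_od", "plate_od", "fluorescence"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DegenerateInputError(
                    f"calibration point {name} must be finite and >= 0, got {v!r}"
                )


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line y = slope*x + intercept with the OD window it is valid on."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    range_lo: float
    range_hi: float
    excluded_points: tuple = field(default_factory=tuple)


class ODConversion(NamedTuple):
    value: float
    out_of_range: bool


@dataclass(frozen=True)
class PlateTypeComparison:
    slope_ratio: float
    ci_low: float
    ci_high: float
    margin: float
    verdict: str  # "equivalent" | "different"
    n_boot: int


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 by ordinary least squares.

    R^2 = 1 - SS_res/SS_tot; a zero SS_tot (constant y) is degenerate.
    """
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("constant response: R-squared is undefined")
    return float(res.slope), float(res.intercept), 1.0 - ss_res / ss_tot


def fit_line(points: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Ordinary least-squares line through (x, y) pairs.

    Requires at least 3 points with non-zero x variance; a constant
    response is rejected as degenerate (its R-squared is undefined).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise DegenerateInputError(f"need >= 3 points for a line fit, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("zero variance in x: slope is undefined")
    slope, intercept, r2 = _ols(x, y)
    return CalibrationFit(
        slope=slope, intercept=intercept, r_squared=r2, n_points=len(pts),
        range_lo=float(x.min()), range_hi=float(x.max()),
    )


def detect_linear_range(
    points: Sequence[CalibrationPoint],
    r2_threshold: float = 0.98,
    axis: str = "plate_od_vs_cuvette",
    blank_sd: Optional[float] = None,
    min_points: int = 4,
) -> CalibrationFit:
    """Find the OD window where the chosen response is linear in cuvette OD.

    Saturation compresses the top of the series, so points are removed
    greedily from the highest cuvette OD downward until the OLS fit over
    the remainder reaches ``r2_threshold``.  ``range_hi`` is the largest
    retained cuvette OD.  ``range_lo`` is the smallest point whose signal
    exceeds 3x ``blank_sd`` when a blank SD is supplied, else the smallest
    retained point.  Removed points are listed in ``excluded_points``.

    ``axis`` selects the response: ``plate_od_vs_cuvette`` (y = plate OD)
    or ``fluorescence_vs_od`` (y = PI fluorescence); x is cuvette OD in
    both cases.
    """
    if axis not in ("plate_od_vs_cuvette", "fluorescence_vs_od"):
        raise ValueError(f"unknown axis {axis!r}")
    pts = sorted(points, key=lambda p: p.cuvette_od)
    if len(pts) < min_points:
        raise DegenerateInputError(
            f"need >= {min_points} calibration points, got {len(pts)}"
        )

    def response(p: CalibrationPoint) -> float:
        return p.plate_od if axis == "plate_od_vs_cuvette" else p.fluorescence

    excluded: list[CalibrationPoint] = []
    kept = list(pts)
    while True:
        if len(kept) < min_points:
            raise NoLinearRangeError(
                f"no subset of >= {min_points} points reaches "
                f"R-squared {r2_threshold}"
            )
        x = np.array([p.cuvette_od for p in kept])
        y = np.array([response(p) for p in kept])
        if np.ptp(x) == 0.0:
            raise DegenerateInputError("zero variance in cuvette OD")
        slope, intercept, r2 = _ols(x, y)
        if r2 >= r2_threshold:
            break
        excluded.append(kept.pop())  # drop the highest-OD point

    range_hi = kept[-1].cuvette_od
    range_lo = kept[0].cuvette_od
    if blank_sd is not None and blank_sd > 0:
        above = [p.cuvette_od for p in kept if response(p) > 3.0 * blank_sd]
        if above:
            range_lo = min(above)
    return CalibrationFit(
        slope=slope, intercept=intercept, r_squared=r2, n_points=len(kept),
        range_lo=float(range_lo), range_hi=float(range_hi),
        excluded_points=tuple(excluded),
    )


def convert_od(value: float, fit: CalibrationFit,
               direction: str = "plate_to_cuvette") -> ODConversion:
    """Convert between plate OD and cuvette OD via the affine calibration.

    The fit maps cuvette OD (x) to plate OD (y).  Out-of-window inputs are
    converted anyway and flagged ``out_of_range`` rather than rejected.
    """
    if fit.slope == 0.0:
        raise NonInvertibleError("zero-slope calibration cannot be inverted")
    if direction == "plate_to_cuvette":
        cuvette = (value - fit.intercept) / fit.slope
        converted = cuvette
    elif direction == "cuvette_to_plate":
        cuvette = value
        converted = fit.slope * value + fit.intercept
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out = not (fit.range_lo <= cuvette <= fit.range_hi)
    return ODConversion(float(converted), out)


def _boot_slopes(x: np.ndarray, y: np.ndarray, n_boot: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized bootstrap of OLS slopes by resampling points."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    mx = xs.mean(axis=1)
    var = (xs * xs).mean(axis=1) - mx * mx
    cov = (xs * ys).mean(axis=1) - mx * ys.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(var > 0, cov / var, np.nan)
    return slopes


def compare_plate_types(
    fit_black: CalibrationFit,
    points_black: Sequence[CalibrationPoint],
    fit_clear: CalibrationFit,
    points_clear: Sequence[CalibrationPoint],
    axis: str = "fluorescence_vs_od",
    margin: float = 0.20,
    n_boot: int = 1000,
    seed: int = 0,
) -> PlateTypeComparison:
    """Are black and clear microplates interchangeable for this assay?

    Compares calibration slopes as a ratio (clear/black) with a bootstrap
    95% CI (resampling points within each plate type).  The verdict is
    ``equivalent`` when the whole CI lies inside the equivalence band
    [1 - margin, 1 + margin] — practical interchangeability, not a
    null-hypothesis test.
    """
    lo = max(fit_black.range_lo, fit_clear.range_lo)
    hi = min(fit_black.range_hi, fit_clear.range_hi)
    if lo >= hi:
        raise IncomparableError(
            f"calibration ranges do not overlap: black [{fit_black.range_lo}, "
            f"{fit_black.range_hi}] vs clear [{fit_clear.range_lo}, {fit_clear.range_hi}]"
        )
    if fit_black.slope == 0.0:
        raise NonInvertibleError("black-plate slope is zero; ratio undefined")

    def response(p: CalibrationPoint) -> float:
        return p.plate_od if axis == "plate_od_vs_cuvette" else p.fluorescence

    rng = np.random.default_rng(seed)
    ratio = fit_clear.slope / fit_black.slope
    xb = np.array([p.cuvette_od for p in points_black])
    yb = np.array([response(p) for p in points_black])
    xc = np.array([p.cuvette_od for p in points_clear])
    yc = np.array([response(p) for p in points_clear])
    sb = _boot_slopes(xb, yb, n_boot, rng)
    sc = _boot_slopes(xc, yc, n_boot, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = sc / sb
    ci_low, ci_high = np.nanpercentile(ratios, [2.5, 97.5])
    verdict = "equivalent" if (1 - margin) <= ci_low and ci_high <= (1 + margin) \
        else "different"
    return PlateTypeComparison(
        slope_ratio=float(ratio), ci_low=float(ci_low), ci_high=float(ci_high),
        margin=margin, verdict=verdict, n_boot=n_boot,
    )
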