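"""The PICLS survival statistic, survival-curve assembly, and mortality fits.

The core statistic normalizes each well's PI fluorescence by its OD600 and
places it between the two on-plate controls — unstained live cells
(defines 100% survival) and boiled dead cells (defines 0% survival):

    Survival = (1 - (I_ij/OD_ij - I_c/OD_c) / (I_D/OD_D - I_c/OD_c)) * 100%

where I_ij/OD_ij are the sample well's readings, I_c/OD_c the unstained
negative-control means and I_D/OD_D the boiled positive-control means of
the same plate at the same age day.  The statistic is absolute (no day-1
normalization), unlike the outgrowth comparator, which expresses 24 h
regrowth OD relative to the day-1 regrowth of the same condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    BelowRangeError,
    InsufficientDataError,
    InvalidAnchorError,
    InvalidPlateError,
    UnidentifiableError,
)
from .plate_io import Condition, ControlSummary, Role, WellRecord, summarize_controls

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalValue",
    "SurvivalPoint",
    "SurvivalCurve",
    "MortalityFit",
    "CurveSummary",
    "OD_FLOOR",
    "picls_survival",
    "outgrowth_survival",
    "build_survival_curve",
    "fit_mortality_model",
    "curve_summaries",
]

#: validated lower OD bound for I/OD normalization (bottom of the
#: calibration window); wells below it are excluded, not zero-filled.
OD_FLOOR = 0.05


class SurvivalValue(NamedTuple):
    """Per-well survival: raw formula value, clamped percentage, clamp flag."""

    raw: float
    pct: float
    clamped: bool


@dataclass(frozen=True)
class SurvivalPoint:
    """Replicate-aggregated survival of one condition at one age day."""

    condition: Condition
    age_day: int
    survival_pct: float      # mean of clamped per-well values, in [0, 100]
    survival_raw: float      # mean of unclamped per-well values
    sd_pct: float
    n_wells: int
    method: str              # "picls" | "outgrowth_liquid"
    values: tuple[float, ...] = field(default_factory=tuple, repr=False)

    def __post_init__(self):
        if not (0.0 <= self.survival_pct <= 100.0):
            raise ValueError("aggregated survival_pct must lie in [0, 100]")
        if self.n_wells < 1 or self.sd_pct < 0:
            raise ValueError("need n_wells >= 1 and sd_pct >= 0")


@dataclass(frozen=True)
class SurvivalCurve:
    """Ordered survival points of one condition over chronological age."""

    condition: Condition
    points: tuple[SurvivalPoint, ...]
    anchor_day: int = 1
    method: str = "picls"

    def __post_init__(self):
        days = [p.age_day for p in self.points]
        if days != sorted(set(days)):
            raise ValueError("age days must be strictly increasing")
        if self.anchor_day not in days:
            raise InvalidAnchorError(
                f"curve for {self.condition.label()} lacks the "
                f"day-{self.anchor_day} anchor point"
            )

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(p.age_day for p in self.points)

    @property
    def means(self) -> tuple[float, ...]:
        return tuple(p.survival_pct for p in self.points)

    def point_at(self, day: int) -> SurvivalPoint:
        for p in self.points:
            if p.age_day == day:
                return p
        raise KeyError(f"no survival point at day {day}")


@dataclass(frozen=True)
class MortalityFit:
    """Recovered Weibull decline parameters (shape k, scale lam in days)."""

    k: float
    lam: float
    rss: float


@dataclass(frozen=True)
class CurveSummary:
    auc: float               # trapezoidal area, % x days
    t50: float               # first day survival crosses 50% (interpolated)
    t50_censored: bool       # True when the curve never reaches 50%


def picls_survival(i_well: float, od_well: float, controls: ControlSummary,
                   od_floor: float = OD_FLOOR) -> SurvivalValue:
    """PICLS survival of one well against its plate's control summary.

    Raises :class:`~picls.errors.BelowRangeError` when the well OD is
    below the validated normalization floor and
    :class:`~picls.errors.InvalidPlateError` when the controls are
    inverted.  The raw formula value is retained alongside the [0, 100]
    clamped percentage; clamping is flagged, never silent.
    """
    if od_well < od_floor:
        raise BelowRangeError(
            f"well OD {od_well:.4g} is below the validated floor {od_floor}"
        )
    if not controls.separation_ok:
        raise InvalidPlateError(
            "boiled positive control is not brighter than the unstained "
            "negative control after OD normalization"
        )
    ratio = i_well / od_well
    raw = (1.0 - (ratio - controls.neg_ratio)
           / (controls.pos_ratio - controls.neg_ratio)) * 100.0
    pct = min(100.0, max(0.0, raw))
    return SurvivalValue(raw=raw, pct=pct, clamped=(pct != raw))


def outgrowth_survival(od_day_t: float, od_day1: float) -> SurvivalValue:
    """Outgrowth-comparator survival: regrowth OD relative to day 1 (=100%).

    Both ODs must already be blank-corrected.  Values above the day-1
    anchor are clamped to 100% with a flag.
    """
    if od_day1 <= 0:
        raise InvalidAnchorError(
            f"day-1 outgrowth OD must be positive after blank correction, "
            f"got {od_day1:.4g}"
        )
    raw = 100.0 * od_day_t / od_day1
    pct = min(100.0, max(0.0, raw))
    return SurvivalValue(raw=raw, pct=pct, clamped=(pct != raw))


def _aggregate(condition: Condition, day: int, values: list[SurvivalValue],
               method: str) -> SurvivalPoint:
    pcts = np.array([v.pct for v in values])
    raws = np.array([v.raw for v in values])
    sd = float(np.std(pcts, ddof=1)) if pcts.size > 1 else 0.0
    return SurvivalPoint(
        condition=condition, age_day=day,
        survival_pct=float(np.mean(pcts)), survival_raw=float(np.mean(raws)),
        sd_pct=sd, n_wells=int(pcts.size), method=method,
        values=tuple(float(x) for x in np.sort(pcts)),
    )


def _blank_od(records: list[WellRecord]) -> float:
    blanks = [r.od600 for r in records if r.role is Role.blank]
    return float(np.mean(blanks)) if blanks else 0.0


def build_survival_curve(
    records: Iterable[WellRecord],
    method: str = "picls",
    controls: Optional[Mapping[tuple[str, int], ControlSummary]] = None,
    od_floor: float = OD_FLOOR,
    anchor_day: int = 1,
    min_controls: int = 3,
) -> dict[Condition, SurvivalCurve]:
    """Assemble per-condition survival curves from well records.

    For ``method="picls"``, controls are taken per (plate, age day) from
    *controls* or summarized from the records themselves; per-well
    survival is computed and then averaged (mean +/- SD) across replicate
    wells of each (condition, age day).  Wells below the OD floor are
    excluded with a warning.  For ``method="outgrowth_liquid"``, well OD
    is blank-corrected (when blanks exist on the same plate/day) and
    expressed relative to the condition's mean day-1 OD.

    Every curve must contain the day-1 anchor point; a condition observed
    only at later days raises :class:`~picls.errors.InvalidAnchorError`.
    """
    if method not in ("picls", "outgrowth_liquid"):
        raise ValueError(f"unknown method {method!r}")
    recs = list(records)
    by_plate_day: dict[tuple[str, int], list[WellRecord]] = {}
    for r in recs:
        by_plate_day.setdefault((r.plate_id, r.age_day), []).append(r)

    per_well: dict[Condition, dict[int, list[SurvivalValue]]] = {}

    if method == "picls":
        for key, group in by_plate_day.items():
            samples = [r for r in group if r.role is Role.sample]
            if not samples:
                continue
            if controls is not None and key in controls:
                csum = controls[key]
            else:
                try:
                    csum = summarize_controls(group, min_controls=min_controls)
                except InvalidPlateError:
                    raise
                except Exception as exc:
                    raise InvalidPlateError(
                        f"plate {key[0]} day {key[1]}: controls unavailable "
                        f"({exc})"
                    ) from exc
            for r in samples:
                if r.od600 < od_floor:
                    logger.warning(
                        "plate %s day %d well %s: OD %.4g below floor %.3g; "
                        "well excluded", r.plate_id, r.age_day, r.well,
                        r.od600, od_floor)
                    continue
                sv = picls_survival(r.fluorescence, r.od600, csum, od_floor)
                per_well.setdefault(r.condition, {}).setdefault(r.age_day, []).append(sv)
    else:
        # outgrowth: blank-correct, then anchor each condition at day 1
        corrected: dict[Condition, dict[int, list[float]]] = {}
        for key, group in by_plate_day.items():
            blank = _blank_od(group)
            if blank == 0.0:
                logger.info("plate %s day %d: no blank wells; OD used "
                            "uncorrected", *key)
            for r in group:
                if r.role is not Role.sample:
                    continue
                corrected.setdefault(r.condition, {}).setdefault(
                    r.age_day, []).append(max(r.od600 - blank, 0.0))
        for cond, by_day in corrected.items():
            if anchor_day not in by_day:
                raise InvalidAnchorError(
                    f"condition {cond.label()} has no day-{anchor_day} "
                    f"outgrowth wells"
                )
            od1 = float(np.mean(by_day[anchor_day]))
            for day, ods in by_day.items():
                per_well.setdefault(cond, {})[day] = [
                    outgrowth_survival(od, od1) for od in ods
                ]

    curves: dict[Condition, SurvivalCurve] = {}
    meth = method if method == "picls" else "outgrowth_liquid"
    for cond, by_day in per_well.items():
        points = tuple(
            _aggregate(cond, day, vals, meth)
            for day, vals in sorted(by_day.items())
        )
        if anchor_day not in [p.age_day for p in points]:
            raise InvalidAnchorError(
                f"condition {cond.label()} has no day-{anchor_day} anchor point"
            )
        curves[cond] = SurvivalCurve(condition=cond, points=points,
                                     anchor_day=anchor_day, method=meth)
    return curves


def fit_mortality_model(curve: SurvivalCurve) -> MortalityFit:
    """Least-squares Weibull fit V(t) = exp(-((t-1)/lam)^k) to a curve.

    Fits the viable fraction (survival_pct / 100) over post-anchor days.
    Initialization is deterministic: k starts at 1 and lam at the
    interpolated age (minus the anchor) where the curve crosses 1/e,
    falling back to the mean post-anchor age; parameters are optimized in
    log space so positivity is structural.  Requires at least 3
    post-anchor days with survival strictly inside (0, 100); a flat curve
    at 100% or 0% is unidentifiable.
    """
    pts = [(float(p.age_day), p.survival_pct / 100.0)
           for p in curve.points if p.age_day > curve.anchor_day]
    interior = [(t, s) for t, s in pts if 0.0 < s < 1.0]
    if len(interior) < 3:
        raise UnidentifiableError(
            "need >= 3 post-anchor days with survival strictly between 0% "
            "and 100% to identify mortality parameters"
        )
    t = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])

    # deterministic init: crossing of 1/e gives lam directly
    lam0 = None
    target = float(np.exp(-1.0))
    days = [curve.anchor_day] + [p[0] for p in pts]
    surv = [1.0] + [p[1] for p in pts]
    for (d0, s0), (d1, s1) in zip(zip(days, surv), zip(days[1:], surv[1:])):
        if s0 >= target >= s1 and s0 != s1:
            lam0 = d0 + (s0 - target) / (s0 - s1) * (d1 - d0) - curve.anchor_day
            break
    if lam0 is None or lam0 <= 0:
        lam0 = max(float(np.mean(t)) - curve.anchor_day, 0.5)

    def residuals(theta):
        k, lam = np.exp(theta)
        return np.exp(-(((t - curve.anchor_day) / lam) ** k)) - s

    sol = least_squares(residuals, x0=np.log([1.0, lam0]), method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    k, lam = np.exp(sol.x)
    return MortalityFit(k=float(k), lam=float(lam),
                        rss=float(np.sum(sol.fun ** 2)))


def curve_summaries(curve: SurvivalCurve) -> CurveSummary:
    """Longevity effect sizes: trapezoidal AUC and interpolated t50.

    t50 is the first age at which mean survival crosses 50% (linear
    interpolation between adjacent days).  A curve that never reaches 50%
    is censored at its last observed day; a curve already below 50% at its
    first day reports that day.
    """
    if len(curve.points) < 2:
        raise InsufficientDataError("curve summaries need >= 2 age days")
    days = np.array(curve.days, dtype=float)
    means = np.array(curve.means, dtype=float)
    auc = float(np.trapezoid(means, days))

    if means[0] <= 50.0:
        return CurveSummary(auc=auc, t50=float(days[0]), t50_censored=False)
    for i in range(len(days) - 1):
        s0, s1 = means[i], means[i + 1]
        if s0 > 50.0 >= s1:
            t50 = days[i] + (s0 - 50.0) / (s0 - s1) * (days[i + 1] - days[i])
            return CurveSummary(auc=auc, t50=float(t50), t50_censored=False)
    return CurveSummary(auc=auc, t50=float(days[-1]), t50_censored=True)
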