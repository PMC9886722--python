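"""Assay-quality metrics: Z-factor, replicate dispersion, plate QC verdicts.

The Z-factor (Zhang's screening-window coefficient) measures how well an
intervention arm separates from the untreated arm given both arms'
spread:

    Z = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

Z in [0.5, 1.0] denotes an excellent high-throughput assay, [0, 0.5) a
marginal one, and Z < 0 an unusable one.  The statistic is computed on
the raw PI fluorescence channel by default; OD-normalized fluorescence
(I/OD, the quantity the survival formula uses) or ``survival_pct`` can
be selected instead when well-to-well density variation dominates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import InsufficientReplicatesError, UndefinedSeparationError
from .plate_io import Condition, ControlSummary, Role, WellRecord, summarize_controls
from .survival import OD_FLOOR, picls_survival

__all__ = [
    "ZFactorResult",
    "ConditionQC",
    "PlateQCReport",
    "z_factor",
    "classify_assay_quality",
    "plate_qc",
]


@dataclass(frozen=True)
class ZFactorResult:
    z: float
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    n_p: int
    n_n: int
    signal: str = "fluorescence"

    @property
    def quality(self) -> str:
        return classify_assay_quality(self.z)


def z_factor(pos_values: Sequence[float], neg_values: Sequence[float],
             signal: str = "fluorescence") -> ZFactorResult:
    """Zhang screening-window coefficient between two replicate arms.

    Uses sample (n-1) standard deviations, appropriate for small-n
    screening plates.  Requires >= 3 values per arm; identical arm means
    leave the window undefined.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 3 or neg.size < 3:
        raise InsufficientReplicatesError(
            f"Z-factor needs >= 3 values per arm, got {pos.size} and {neg.size}"
        )
    mu_p, mu_n = float(np.mean(pos)), float(np.mean(neg))
    if mu_p == mu_n:
        raise UndefinedSeparationError(
            "arm means are identical; the screening window is undefined"
        )
    sigma_p = float(np.std(pos, ddof=1))
    sigma_n = float(np.std(neg, ddof=1))
    z = 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)
    return ZFactorResult(z=z, mu_p=mu_p, sigma_p=sigma_p, mu_n=mu_n,
                         sigma_n=sigma_n, n_p=int(pos.size), n_n=int(neg.size),
                         signal=signal)


def classify_assay_quality(z: float) -> str:
    """Map a Z-factor to the standard quality bands.

    >= 0.5 excellent, [0, 0.5) marginal, < 0 unusable.
    """
    if z > 1.0:
        raise ValueError("Z-factor cannot exceed 1")
    if z >= 0.5:
        return "excellent"
    if z >= 0.0:
        return "marginal"
    return "unusable"


@dataclass(frozen=True)
class ConditionQC:
    condition: Condition
    cv: float
    n_wells: int


@dataclass(frozen=True)
class PlateQCReport:
    plate_id: str
    age_day: int
    verdict: str  # "pass" | "warn" | "fail"
    reasons: tuple[str, ...]
    control_separation_ok: bool
    condition_cvs: tuple[ConditionQC, ...]
    n_below_floor: int
    n_clamped: int


def plate_qc(
    records: Iterable[WellRecord],
    controls: Optional[Mapping[tuple[str, int], ControlSummary]] = None,
    cv_warn: float = 0.20,
    cv_fail: float = 0.35,
    od_floor: float = OD_FLOOR,
    min_controls: int = 3,
) -> list[PlateQCReport]:
    """Per-plate, per-age-day quality report (always produced, never raises).

    Flags: inverted controls (fail), replicate CV of I/OD per condition
    above ``cv_fail`` (fail) or ``cv_warn`` (warn), plus informational
    counts of below-OD-floor wells and wells whose raw survival fell
    outside [0, 100] and was clamped.
    """
    by_plate_day: dict[tuple[str, int], list[WellRecord]] = {}
    for r in records:
        by_plate_day.setdefault((r.plate_id, r.age_day), []).append(r)

    reports = []
    for (plate_id, day), group in sorted(by_plate_day.items()):
        reasons: list[str] = []
        sep_ok = True
        csum: Optional[ControlSummary] = None
        if controls is not None and (plate_id, day) in controls:
            csum = controls[(plate_id, day)]
            sep_ok = csum.separation_ok
        else:
            try:
                csum = summarize_controls(group, min_controls=min_controls,
                                          strict=False)
                sep_ok = csum.separation_ok
            except Exception as exc:
                sep_ok = False
                reasons.append(f"controls unavailable: {exc}")
        if csum is not None and not sep_ok:
            reasons.append(
                "control separation violated: boiled control not brighter "
                "than unstained control after OD normalization"
            )

        samples = [r for r in group if r.role is Role.sample]
        n_below = sum(1 for r in samples if r.od600 < od_floor)
        if n_below:
            reasons.append(f"{n_below} sample wells below OD floor {od_floor}")

        cond_vals: dict[Condition, list[float]] = {}
        for r in samples:
            if r.od600 >= od_floor:
                cond_vals.setdefault(r.condition, []).append(r.norm_fluorescence)
        cvs: list[ConditionQC] = []
        worst = 0.0
        for cond, vals in sorted(cond_vals.items(), key=lambda kv: str(kv[0])):
            arr = np.asarray(vals)
            cv = float(np.std(arr, ddof=1) / np.mean(arr)) if arr.size > 1 else 0.0
            cvs.append(ConditionQC(condition=cond, cv=cv, n_wells=arr.size))
            worst = max(worst, cv)
            if cv >= cv_fail:
                reasons.append(
                    f"condition {cond.label()}: replicate CV {cv:.0%} >= "
                    f"fail threshold {cv_fail:.0%}"
                )
            elif cv >= cv_warn:
                reasons.append(
                    f"condition {cond.label()}: replicate CV {cv:.0%} >= "
                    f"warn threshold {cv_warn:.0%}"
                )

        n_clamped = 0
        if csum is not None and sep_ok:
            for r in samples:
                if r.od600 < od_floor:
                    continue
                if picls_survival(r.fluorescence, r.od600, csum, od_floor).clamped:
                    n_clamped += 1

        if not sep_ok or worst >= cv_fail:
            verdict = "fail"
        elif worst >= cv_warn or n_below:
            verdict = "warn"
        else:
            verdict = "pass"
        reports.append(PlateQCReport(
            plate_id=plate_id, age_day=day, verdict=verdict,
            reasons=tuple(reasons), control_separation_ok=sep_ok,
            condition_cvs=tuple(cvs), n_below_floor=n_below,
            n_clamped=n_clamped,
        ))
    return reports
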