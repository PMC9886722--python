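"""Screen-level analysis: growth (toxicity) gate, hit calling, dose-response.

A compound is called a lifespan-extension *hit* when its mean survival
exceeds the untreated control's by at least a threshold (default 15
percentage points) with a bootstrap 95% CI above zero at two or more
consecutive age days, after a growth gate has excluded compounds that
inhibit outgrowth of the culture (which would confound the aging
readout).  Family-wise error across compounds is controlled by Holm
step-down on the decision-day bootstrap p-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, MissingDataError
from .plate_io import Condition
from .survival import SurvivalCurve, curve_summaries

__all__ = [
    "GrowthVerdict",
    "HitConfig",
    "HitCall",
    "DoseResponseTable",
    "growth_check",
    "call_hits",
    "summarize_dose_response",
]


@dataclass(frozen=True)
class GrowthVerdict:
    """Condition/control OD ratios at the growth time points and a status.

    ``inhibited``: below threshold at the final (72 h) time point;
    ``slowed_growth``: below threshold early but recovered by the final
    point (the pattern of a mild TORC1 inhibitor dose); else ``normal``.
    """

    condition: Condition
    ratios: dict[int, float]
    status: str  # "normal" | "slowed_growth" | "inhibited"


@dataclass(frozen=True)
class HitConfig:
    delta_threshold: float = 15.0   # percentage points over control
    alpha: float = 0.05
    n_boot: int = 1000
    min_consecutive_days: int = 2
    min_replicates: int = 3
    adjusted: bool = True           # Holm step-down across compounds
    seed: int = 0


@dataclass(frozen=True)
class HitCall:
    compound: str
    concentration: Optional[float]
    concentration_unit: Optional[str]
    decision: str                   # "hit" | "no_effect" | "toxic"
    effect_days: tuple[int, ...]    # days meeting the per-day hit rule
    deltas: dict[int, float]        # survival difference vs control, pp
    decision_day: int
    ci_low: float                   # bootstrap 95% CI of delta, decision day
    ci_high: float
    p_value: float
    p_adjusted: Optional[float]
    adjusted: bool
    seed: int


@dataclass(frozen=True)
class DoseResponseTable:
    compound: str
    table: pd.DataFrame             # one row per concentration, ordered
    trend_rho: float                # Spearman rho of AUC vs concentration
    trend_p: float


def growth_check(growth: pd.DataFrame, threshold: float = 0.8) -> dict[Condition, GrowthVerdict]:
    """Gate conditions on growth-phase OD relative to the untreated control.

    *growth* is a tidy table with columns ``compound`` (null for the
    control), ``concentration``, ``time_h``, ``od600`` and optionally
    ``concentration_unit``.  For each condition the per-time-point ratio
    of mean OD to the control mean is computed; a ratio below *threshold*
    at the last time point marks the condition ``inhibited``, below
    threshold only at earlier points ``slowed_growth``, else ``normal``.
    """
    df = growth.copy()
    if "concentration_unit" not in df.columns:
        df["concentration_unit"] = None
    ctrl = df[df["compound"].isna()]
    if ctrl.empty:
        raise MissingDataError("growth table has no untreated control wells")
    ctrl_mean = ctrl.groupby("time_h")["od600"].mean()

    verdicts: dict[Condition, GrowthVerdict] = {}
    treated = df[df["compound"].notna()]
    for (comp, conc, unit), grp in treated.groupby(
            ["compound", "concentration", "concentration_unit"], dropna=False):
        cond = Condition(comp, None if pd.isna(conc) else float(conc),
                         None if pd.isna(unit) else unit)
        ratios: dict[int, float] = {}
        for t, sub in grp.groupby("time_h"):
            if t not in ctrl_mean.index:
                raise MissingDataError(
                    f"no control growth wells at time point {t} h"
                )
            ratios[int(t)] = float(sub["od600"].mean() / ctrl_mean[t])
        times = sorted(ratios)
        if ratios[times[-1]] < threshold:
            status = "inhibited"
        elif any(ratios[t] < threshold for t in times[:-1]):
            status = "slowed_growth"
        else:
            status = "normal"
        verdicts[cond] = GrowthVerdict(condition=cond, ratios=ratios,
                                       status=status)
    return verdicts


def _bootstrap_delta(treat: np.ndarray, ctrl: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Bootstrap distribution of mean(treat*) - mean(ctrl*), resampling wells."""
    ti = rng.integers(0, treat.size, size=(n_boot, treat.size))
    ci = rng.integers(0, ctrl.size, size=(n_boot, ctrl.size))
    return treat[ti].mean(axis=1) - ctrl[ci].mean(axis=1)


def call_hits(
    curves: Mapping[Condition, SurvivalCurve],
    config: HitConfig = HitConfig(),
    growth_verdicts: Optional[Mapping[Condition, GrowthVerdict]] = None,
) -> list[HitCall]:
    """Call lifespan-extension hits against the untreated control curve.

    For each treated condition, per-day survival differences vs control
    are computed with a bootstrap 95% CI (resampling wells within each
    arm; well values are sorted first so the decision is invariant to
    well ordering and plate relabeling).  A condition is a hit when the
    per-day rule — CI above zero and delta >= ``delta_threshold`` — holds
    at >= ``min_consecutive_days`` consecutive post-anchor days, its
    (Holm-adjusted, when ``adjusted``) decision-day p-value clears
    ``alpha``, and the growth gate did not mark it inhibited.  Inhibited
    conditions are reported ``toxic`` without a longevity call.
    """
    control = next((c for cond, c in curves.items() if cond.is_control), None)
    if control is None:
        raise MissingDataError("no untreated control curve in the screen")

    rng = np.random.default_rng(config.seed)
    provisional = []
    for cond, curve in sorted(curves.items(), key=lambda kv: str(kv[0])):
        if cond.is_control:
            continue
        shared = [d for d in curve.days
                  if d in control.days and d > curve.anchor_day]
        shared.sort()
        if len(shared) < 2:
            raise InsufficientDataError(
                f"condition {cond.label()}: fewer than 2 post-anchor age "
                f"days shared with the control"
            )
        for d in shared:
            for arm_curve in (curve, control):
                if arm_curve.point_at(d).n_wells < config.min_replicates:
                    raise InsufficientDataError(
                        f"day {d}: fewer than {config.min_replicates} "
                        f"replicate wells"
                    )
        deltas: dict[int, float] = {}
        cis: dict[int, tuple[float, float]] = {}
        for d in shared:
            tvals = np.sort(np.asarray(curve.point_at(d).values))
            cvals = np.sort(np.asarray(control.point_at(d).values))
            deltas[d] = float(tvals.mean() - cvals.mean())
            boot = _bootstrap_delta(tvals, cvals, config.n_boot, rng)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            cis[d] = (float(lo), float(hi))
        qualifying = [d for d in shared
                      if cis[d][0] > 0.0 and deltas[d] >= config.delta_threshold]
        # consecutive = adjacent in the ordered list of shared days
        run, best_run = [], []
        for d in shared:
            if d in qualifying:
                run.append(d)
                if len(run) > len(best_run):
                    best_run = list(run)
            else:
                run = []
        passes_days = len(best_run) >= config.min_consecutive_days
        decision_pool = best_run if best_run else shared
        decision_day = max(decision_pool, key=lambda d: deltas[d])
        # one-sided bootstrap p at the decision day
        tvals = np.sort(np.asarray(curve.point_at(decision_day).values))
        cvals = np.sort(np.asarray(control.point_at(decision_day).values))
        boot = _bootstrap_delta(tvals, cvals, config.n_boot, rng)
        p = (1.0 + float(np.sum(boot <= 0.0))) / (config.n_boot + 1.0)
        provisional.append((cond, deltas, cis, tuple(qualifying), passes_days,
                            decision_day, p))

    p_adj: dict[Condition, float] = {}
    if config.adjusted and provisional:
        pvals = [p for *_, p in provisional]
        _, adj, _, _ = multipletests(pvals, alpha=config.alpha, method="holm")
        p_adj = {cond: float(a)
                 for (cond, *_), a in zip(provisional, adj)}

    calls = []
    for cond, deltas, cis, qualifying, passes_days, decision_day, p in provisional:
        growth = growth_verdicts.get(cond) if growth_verdicts else None
        if growth is not None and growth.status == "inhibited":
            decision = "toxic"
        else:
            significant = (p_adj.get(cond, p) if config.adjusted else p) <= config.alpha
            decision = "hit" if (passes_days and significant) else "no_effect"
        lo, hi = cis[decision_day]
        calls.append(HitCall(
            compound=cond.compound, concentration=cond.concentration,
            concentration_unit=cond.unit, decision=decision,
            effect_days=qualifying, deltas=deltas, decision_day=decision_day,
            ci_low=lo, ci_high=hi, p_value=p,
            p_adjusted=p_adj.get(cond), adjusted=config.adjusted,
            seed=config.seed,
        ))
    return calls


def summarize_dose_response(
    curves: Mapping[Condition, SurvivalCurve],
    compound: Optional[str] = None,
) -> DoseResponseTable:
    """Concentration-ordered survival table for one compound's series.

    The untreated control enters as concentration 0.  Rows carry per-day
    mean +/- SD plus AUC and t50; the monotone-trend annotation is the
    Spearman correlation of AUC with concentration (0 when all AUCs tie).
    """
    rows = []
    compounds = {c.compound for c in curves if not c.is_control}
    if compound is None:
        if len(compounds) > 1:
            raise InsufficientDataError(
                f"dose-response table is per compound; found {sorted(compounds)}"
            )
        compound = next(iter(compounds)) if compounds else ""
    selected = {c: crv for c, crv in curves.items()
                if c.is_control or c.compound == compound}
    if len(selected) < 2:
        warnings.warn(
            f"dose-response for {compound!r}: fewer than 2 concentrations "
            f"(including control); table is degenerate", stacklevel=2)

    for cond, curve in selected.items():
        conc = 0.0 if cond.is_control else float(cond.concentration or 0.0)
        summ = curve_summaries(curve)
        row: dict = {"compound": compound, "concentration": conc,
                     "auc": summ.auc,
                     "t50": summ.t50, "t50_censored": summ.t50_censored}
        for p in curve.points:
            row[f"day{p.age_day}_mean"] = p.survival_pct
            row[f"day{p.age_day}_sd"] = p.sd_pct
            row[f"day{p.age_day}_n"] = p.n_wells
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("concentration").reset_index(drop=True)

    if len(table) > 1 and table["auc"].nunique() > 1:
        rho, pval = sp_stats.spearmanr(table["concentration"], table["auc"])
        rho = 0.0 if np.isnan(rho) else float(rho)
        pval = float(pval) if np.isfinite(pval) else 1.0
    else:
        rho, pval = 0.0, 1.0
    return DoseResponseTable(compound=compound, table=table,
                             trend_rho=rho, trend_p=pval)
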