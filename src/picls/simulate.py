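"""Ground-truth simulator for PI/OD plate screens.

Viability in stationary phase is modelled with a Weibull hazard starting
at day 1 (the 72 h growth time point):

    V(t) = exp(-((t - 1) / lam) ** k),   t >= 1,   V(1) = 1

with shape ``k`` (k > 1 gives an accelerating death rate, as observed for
chronologically aging yeast) and scale ``lam`` in days.  An exponential
decline through a ~50% day-4 point would predict ~25% at day 7, too high
for the observed sub-20% survival of untreated cultures; k = 1.3
reconciles both, so the default arms share k = 1.3 and differ in ``lam``.

The measurement model turns a true culture density (cuvette-equivalent
OD600) and a viable fraction into plate-reader readings: PI fluorescence
is proportional to cell density with gain ``f_bg`` (a.u. per OD) for live
cells and ``f_dead`` for PI-stained dead cells, so I/OD normalization in
the survival statistic cancels density; plate OD600 is linear up to a
saturation knee (default cuvette OD 12) and compressed above it; both
channels carry independent multiplicative Gaussian noise with coefficient
of variation ``cv``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import AssayDesignError, DataValidationError
from .calibration import CalibrationPoint
from .plate_io import Role, WellRecord

__all__ = [
    "MortalityModel",
    "MeasurementModel",
    "Arm",
    "ScreenDesign",
    "viability",
    "saturate",
    "simulate_well",
    "simulate_plate",
    "simulate_growth",
    "simulate_outgrowth",
    "simulate_dilution_series",
    "default_screen",
]


@dataclass(frozen=True)
class MortalityModel:
    """Weibull viability decline V(t) = exp(-((t-1)/lam)^k), anchored V(1)=1."""

    k: float
    lam: float

    def __post_init__(self):
        if not (self.k > 0 and self.lam > 0):
            raise DataValidationError(
                f"Weibull parameters must be positive, got k={self.k}, lam={self.lam}"
            )


@dataclass(frozen=True)
class MeasurementModel:
    """Plate-reader physics: channel gains, OD saturation knee, noise CV."""

    f_bg: float = 50.0       # unstained-cell fluorescence, a.u. per OD
    f_dead: float = 1050.0   # PI-stained dead-cell fluorescence, a.u. per OD
    od_knee: float = 12.0    # cuvette OD where plate OD starts saturating
    sat_exponent: float = 0.7
    cv: float = 0.05         # multiplicative noise coefficient, per channel

    def __post_init__(self):
        if not (self.f_dead > self.f_bg > 0):
            raise DataValidationError("require f_dead > f_bg > 0")
        if self.od_knee <= 0 or self.cv < 0:
            raise DataValidationError("require od_knee > 0 and cv >= 0")


@dataclass(frozen=True)
class Arm:
    """One screen condition: its label and its true mortality kinetics.

    ``compound=None`` marks the untreated control arm.  ``growth_ratio``
    maps growth time points (hours) to the arm's OD relative to control,
    used by the growth/toxicity gate simulation.
    """

    compound: Optional[str]
    concentration: Optional[float]
    concentration_unit: Optional[str]
    mortality: MortalityModel
    growth_ratio: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScreenDesign:
    """Arms x age days x replicates, plus per-plate controls."""

    arms: tuple[Arm, ...]
    age_days: tuple[int, ...] = (1, 4, 7, 14, 21)
    n_replicates: int = 6
    n_neg_controls: int = 3
    n_pos_controls: int = 3
    growth_timepoints: tuple[int, ...] = (24, 48, 72)
    sample_od: float = 1.0  # true (cuvette-equivalent) OD of assayed aliquots

    def __post_init__(self):
        if not any(a.compound is None for a in self.arms):
            raise AssayDesignError("screen design must include an untreated control arm")
        if 1 not in self.age_days:
            raise AssayDesignError("age days must include the day-1 anchor")


def viability(model: MortalityModel, day: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Closed-form Weibull viable fraction at chronological age *day* (>= 1)."""
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < 1):
        raise DataValidationError("chronological age starts at day 1")
    out = np.exp(-(((day_arr - 1) / model.lam) ** model.k))
    return float(out) if np.isscalar(day) or out.ndim == 0 else out


def saturate(true_od: Union[float, np.ndarray], knee: float = 12.0,
             exponent: float = 0.7) -> Union[float, np.ndarray]:
    """Plate OD response: identity below the knee, compressed above it.

    saturate(x) = x for x <= knee, else knee + (x - knee)**exponent.
    """
    x = np.asarray(true_od, dtype=float)
    out = np.where(x <= knee, x, knee + np.power(np.maximum(x - knee, 0.0), exponent))
    return float(out) if out.ndim == 0 else out


def _measure(v: float, true_od: float, m: MeasurementModel,
             rng: np.random.Generator, stained: bool = True) -> tuple[float, float]:
    """Noisy (fluorescence, od600) for viable fraction v at density true_od."""
    dead = 1.0 - v
    gain = m.f_bg * v + m.f_dead * dead if stained else m.f_bg
    eps_f, eps_od = rng.normal(0.0, m.cv, size=2) if m.cv > 0 else (0.0, 0.0)
    fluor = gain * true_od * (1.0 + eps_f)
    od = saturate(true_od, m.od_knee, m.sat_exponent) * (1.0 + eps_od)
    return max(fluor, 0.0), max(od, 0.0)


def simulate_well(arm: Arm, day: int, measurement: MeasurementModel,
                  true_od: float, rng: np.random.Generator, *,
                  plate_id: str = "SIM", well: str = "A1",
                  replicate: int = 1) -> WellRecord:
    """One stained sample well of *arm* at age *day*."""
    v = viability(arm.mortality, day)
    fluor, od = _measure(v, true_od, measurement, rng, stained=True)
    return WellRecord(
        plate_id=plate_id, well=well, role=Role.sample,
        compound=arm.compound, concentration=arm.concentration,
        concentration_unit=arm.concentration_unit, age_day=day,
        replicate=replicate, fluorescence=fluor, od600=od,
    )


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def simulate_plate(design: ScreenDesign, measurement: MeasurementModel,
                   seed: int) -> tuple[list[WellRecord], pd.DataFrame]:
    """Simulate every plate of the screen plus its ground-truth table.

    One plate per age day holds that day's controls (unstained negative
    wells: live cells, no PI gain; boiled positive wells: fully dead) and
    all sample wells; if a day needs more than 96 wells it spills onto
    further plates, each with its own controls.  The same seed yields
    bit-identical records.
    """
    rng = np.random.default_rng(seed)
    names = _well_names()
    n_controls = design.n_neg_controls + design.n_pos_controls
    per_plate = 96 - n_controls
    if per_plate <= 0:
        raise AssayDesignError("control wells alone exceed plate capacity")

    records: list[WellRecord] = []
    truth_rows = []
    for day in design.age_days:
        sample_specs = [
            (arm, rep)
            for arm in design.arms
            for rep in range(1, design.n_replicates + 1)
        ]
        pages = [sample_specs[i:i + per_plate]
                 for i in range(0, len(sample_specs), per_plate)]
        for page_no, page in enumerate(pages, start=1):
            plate_id = f"SIM-d{day:02d}-p{page_no}"
            cursor = 0
            for _ in range(design.n_neg_controls):
                fluor, od = _measure(1.0, design.sample_od, measurement, rng,
                                     stained=False)
                records.append(WellRecord(
                    plate_id=plate_id, well=names[cursor],
                    role=Role.neg_control_unstained, age_day=day,
                    fluorescence=fluor, od600=od))
                cursor += 1
            for _ in range(design.n_pos_controls):
                fluor, od = _measure(0.0, design.sample_od, measurement, rng,
                                     stained=True)
                records.append(WellRecord(
                    plate_id=plate_id, well=names[cursor],
                    role=Role.pos_control_boiled, age_day=day,
                    fluorescence=fluor, od600=od))
                cursor += 1
            for arm, rep in page:
                records.append(simulate_well(
                    arm, day, measurement, design.sample_od, rng,
                    plate_id=plate_id, well=names[cursor], replicate=rep))
                cursor += 1
        for arm in design.arms:
            truth_rows.append({
                "compound": arm.compound, "concentration": arm.concentration,
                "concentration_unit": arm.concentration_unit, "age_day": day,
                "viability": float(viability(arm.mortality, day)),
            })
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_growth(design: ScreenDesign, measurement: MeasurementModel,
                    seed: int, saturation_od: float = 1.0) -> pd.DataFrame:
    """Growth-phase OD600 per arm at the design's growth time points.

    Each arm's OD is the control saturation OD scaled by its
    ``growth_ratio`` at that time point (default 1.0), with the
    measurement model's multiplicative noise.  Used by the growth
    (toxicity) gate, not by survival scoring.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arm in design.arms:
        for t in design.growth_timepoints:
            ratio = arm.growth_ratio.get(t, 1.0)
            for rep in range(1, design.n_replicates + 1):
                eps = rng.normal(0.0, measurement.cv) if measurement.cv > 0 else 0.0
                rows.append({
                    "compound": arm.compound,
                    "concentration": arm.concentration,
                    "concentration_unit": arm.concentration_unit,
                    "time_h": t, "replicate": rep,
                    "od600": max(saturation_od * ratio * (1.0 + eps), 0.0),
                })
    return pd.DataFrame(rows)


def simulate_outgrowth(design: ScreenDesign, measurement: MeasurementModel,
                       seed: int, outgrowth_od: float = 1.2) -> list[WellRecord]:
    """Outgrowth-assay wells: 24 h regrowth OD proportional to viable fraction.

    Regrowth kinetics are not modelled beyond proportionality; fluorescence
    is not read in the outgrowth assay and is recorded as 0.
    """
    rng = np.random.default_rng(seed)
    records = []
    names = _well_names()
    for day in design.age_days:
        plate_id = f"SIM-OG-d{day:02d}"
        cursor = 0
        for arm in design.arms:
            v = viability(arm.mortality, day)
            for rep in range(1, design.n_replicates + 1):
                eps = rng.normal(0.0, measurement.cv) if measurement.cv > 0 else 0.0
                records.append(WellRecord(
                    plate_id=plate_id, well=names[cursor], role=Role.sample,
                    compound=arm.compound, concentration=arm.concentration,
                    concentration_unit=arm.concentration_unit, age_day=day,
                    replicate=rep, fluorescence=0.0,
                    od600=max(outgrowth_od * v * (1.0 + eps), 0.0)))
                cursor += 1
    return records


def simulate_dilution_series(
    measurement: MeasurementModel,
    ods: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Two-fold dilution series of stained dead cells for calibration.

    Defaults to the 11-step series cuvette OD 48 down to ~0.05.  PI
    fluorescence is linear in true density over the whole series (gain
    ``f_dead``); plate OD saturates above the knee.
    """
    if ods is None:
        ods = [48.0 / 2 ** i for i in range(11)]  # 48 ... 0.046875
    rng = np.random.default_rng(seed)
    points = []
    for od in sorted(ods):
        eps_f, eps_od = (rng.normal(0.0, measurement.cv, size=2)
                         if measurement.cv > 0 else (0.0, 0.0))
        points.append(CalibrationPoint(
            cuvette_od=float(od),
            plate_od=float(max(saturate(od, measurement.od_knee,
                                        measurement.sat_exponent) * (1 + eps_od), 0.0)),
            fluorescence=float(max(measurement.f_dead * od * (1 + eps_f), 0.0)),
        ))
    return points


def default_screen(n_replicates: int = 6) -> ScreenDesign:
    """The default simulated screen: emulated geroprotector arms.

    Arm scales are chosen so the closed-form viability reproduces the
    survival trends of the assay's reference interventions: untreated
    (k=1.3, lam=4: ~50% day 4, ~18% day 7), a rapamycin-like arm
    (lam=13: ~69% day 7), a calorie-restriction-like arm (lam=9), a
    long-lived fructose-analog arm (lam=38: ~65% day 21), and an inert
    sugar arm identical to control.
    """
    base = MortalityModel(k=1.3, lam=4.0)
    arms = (
        Arm(None, None, None, base),
        Arm("rapamycin", 5.0, "nM", MortalityModel(k=1.3, lam=13.0)),
        Arm("glucose_restriction", 0.5, "%", MortalityModel(k=1.3, lam=9.0),
            growth_ratio={24: 0.85, 48: 0.85, 72: 0.85}),
        Arm("2,5-AM", 8.0, "mM", MortalityModel(k=1.3, lam=38.0)),
        Arm("sorbitol", 8.0, "mM", base),
    )
    return ScreenDesign(arms=arms, n_replicates=n_replicates)
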