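# Methods

## The survival statistic

PICLS scores each well by placing its OD-normalized PI fluorescence
between two on-plate anchors measured at the same chronological age:

    Survival = (1 − (I/OD − I_c/OD_c) / (I_D/OD_D − I_c/OD_c)) · 100%

`I_c/OD_c` is the mean normalized signal of unstained live-cell wells
(no PI; defines 100% survival) and `I_D/OD_D` that of boiled, stained
wells (fully dead; defines 0%). The statistic is *absolute*: unlike the
outgrowth comparator it needs no day-1 normalization, and the day-1
point on a PICLS curve is purely reporting. The implementation:

- requires controls per plate per age day (controls are stained and
  read on the same plate as the samples they normalize) and uses their
  arithmetic means;
- enforces the separation invariant `I_D/OD_D > I_c/OD_c`; a plate
  violating it is invalid, not silently rescued;
- clamps per-well survival to [0, 100] — measurement noise pushes
  wells outside the interval near the anchors — but keeps the raw value
  and a flag, and aggregates replicates as mean ± sample SD of the
  clamped values;
- excludes wells with OD600 below 0.05 (the bottom of the validated
  calibration window) rather than dividing by a near-zero density.

The outgrowth comparator is `100 · OD_t / OD_day1` on blank-corrected
24 h regrowth ODs, clamped at 100% with a flag; its day-1 anchor is
mandatory.

## Calibration and linear range

Plate OD600 tracks cuvette OD600 linearly only up to a saturation knee
(around cuvette OD 12 for standard 96-well formats); above it the
response is compressed and the assay's normalization is invalid.
`detect_linear_range` trims points greedily from the top of a dilution
series until the OLS fit of the remainder reaches an R² threshold
(default 0.98). Greedy top-down trimming, rather than changepoint
regression, matches the physics: saturation is a monotone compression
at the high end, so the first point to violate linearity is always the
most concentrated one. The procedure is idempotent (re-running on the
retained subset removes nothing) and retains everything on noiseless
linear data. The lower bound is the smallest point whose signal exceeds
3× the blank SD when blanks are available, else the smallest retained
point. Out-of-window OD conversions are flagged, not rejected.

Black and clear microplates are compared as a slope ratio with a
bootstrap 95% CI (resampling calibration points, default 1000 draws,
seeded); the plates are declared interchangeable when the whole CI lies
inside a ±20% equivalence band. This is an equivalence criterion for
practical interchangeability, deliberately not a null-hypothesis test.

## Assay quality

The screening window is Zhang's Z-factor, `1 − 3(σp+σn)/|μp−μn|` with
sample (n−1) SDs, positive arm = intervention wells and negative arm =
untreated wells at the same age day. The signal is the raw PI channel
by default: with independent per-channel noise the I/OD ratio carries
√2 times the per-channel CV, which needlessly narrows the window when
well densities are uniform; I/OD and survival-percent signals are
selectable for plates where density variation dominates. Bands: Z ≥ 0.5
excellent, 0 ≤ Z < 0.5 marginal, Z < 0 unusable. Plate QC flags
inverted controls (fail), per-condition replicate CV of I/OD above 35%
(fail) or 20% (warn) — both thresholds are configuration defaults, not
measured constants — and reports clamped and below-floor well counts.

## Hit calling

Per condition and age day, the effect is the difference in mean
survival vs the untreated control, with a bootstrap 95% percentile CI
from resampling wells within each arm (1000 draws; well values are
sorted before resampling so decisions are invariant to well order and
plate relabeling). A *hit* requires: CI above zero **and** effect ≥ 15
percentage points at ≥ 2 consecutive age days; a one-sided bootstrap
p-value at the decision day (the qualifying day with the largest
effect) below 0.05 after Holm step-down across compounds; and passage
of the growth gate. The 15 pp threshold is a deliberately conservative
codification of effects worth confirming (the emulated geroprotector
arms separate by 30–55 pp); Holm rather than FDR because screens of
hundreds of compounds feed a confirm-by-retest workflow where
family-wise control is the natural guarantee. Both are configurable.

The growth gate compares growth-phase OD (24/48/72 h) to control:
ratio < 0.8 at 72 h marks a condition *inhibited* (reported toxic, no
longevity call — a compound that blocks growth confounds the aging
readout); < 0.8 early but recovered by 72 h marks *slowed growth*
(the signature of a mild TORC1-inhibitor dose) without vetoing the
call.

Dose–response series are summarized per compound (control at
concentration 0) with per-day survival, AUC and t50, and a Spearman
trend of AUC vs concentration; no EC50/Hill fit is attempted on 4–6
point double-dilution grids.

## The simulator

The generator exists so every stage can be tested against known ground
truth. Viability follows a Weibull decline anchored at day 1:

    V(t) = exp(−((t − 1)/λ)^k),  t ≥ 1

An exponential (k = 1) through a ~50% day-4 point would leave ~25% at
day 7, too slow for the observed sub-20% survival of untreated
cultures; shape k = 1.3 (accelerating hazard) reconciles both, so all
default arms share k = 1.3 and differ in scale λ (days): untreated 4.0,
rapamycin-like 13.0, calorie-restriction-like 9.0, fructose-analog-like
38.0, inert sugar 4.0 (identical to control by design). These defaults
are an *emulation* tuned to the survival levels the assay was validated
against (~50% control at day 4, <20% at day 7, ~70% rapamycin-like at
day 7, ~65% long-lived arm at day 21), not measurements.

Measurement model: PI fluorescence is density-proportional,
`(f_bg·V + f_dead·(1−V)) · OD_true`, with gains f_bg = 50 and
f_dead = 1050 a.u. per OD — arbitrary instrument units chosen so the
live:dead brightness ratio is ~21× and the numbers are convenient;
only their ratio matters because the survival formula is scale
invariant. Plate OD is `OD_true` below the knee (default 12) and
`knee + (OD_true − knee)^0.7` above it. Both channels carry independent
multiplicative Gaussian noise with CV 5% (3% for calibration series),
typical of plate readers. Controls are generated from the same model
with V pinned to 1 (no PI gain) or 0. Assay wells use OD_true = 1
(a washed stationary-phase aliquot). Each age day is one simulated
plate carrying its own triplicate controls, spilling onto additional
plates (each with its own controls) past 96 wells; a fixed seed gives
bit-identical output.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: systematic plate-position (edge) effects,
autofluorescence differences between plate types beyond a slope factor,
dye-uptake kinetics in partially permeabilized cells, density variation
between wells, regrowth kinetics beyond OD ∝ viable fraction, and any
mechanistic aging biology (the interventions are nothing but λ
settings).

## Mortality-parameter recovery

`fit_mortality_model` inverts the simulator: least squares of
V(t) = exp(−((t−1)/λ)^k) against survival/100 over post-anchor days,
optimized in log-parameter space (positivity structural, Levenberg–
Marquardt, tolerances 1e−15). Initialization is deterministic: k₀ = 1
and λ₀ from the interpolated crossing of 1/e, falling back to the mean
post-anchor age. At least 3 post-anchor days strictly inside (0, 100)
are required; flat curves are unidentifiable. On noiseless curves the
fit recovers parameters to ~1e−6 relative; under the default noise
(CV 5%, 6 wells/day) the median relative error of λ̂ across 100
simulated screens is a few percent. Deep-tail points clamped at 0
slightly bias k̂ upward; λ̂, the longevity-relevant scale, is robust.

t50 is the first linearly interpolated crossing of 50% mean survival
(a curve never reaching 50% is censored at its last day; one starting
below 50% reports its first day); AUC is trapezoidal over observed
days.

## Problem sizes and determinism

Defaults throughout are chosen so the full test suite and the
acceptance script each run in minutes on one core: screens of 5 arms ×
12 wells for trend checks, 6 wells for power/error-rate studies (500
null screens, 200 power screens, 100 recovery seeds), 1000 bootstrap
draws. Every stochastic component takes an explicit integer seed and
is bit-reproducible; `scripts/acceptance.py` spawns all sub-seeds from
its single `--seed` and reports the stochastic screen quantities as a
mean over 5 replicate screens, which narrows the Monte-Carlo spread
contributed by the triplicate per-plate controls (the dominant noise
term: a 3-well control estimate rescales the whole plate by ~±4%).

## Known limitations

- The linear-range detector assumes saturation only at the top of the
  series; a low-end nonlinearity (e.g. scattering floor) would not be
  trimmed, only excluded via the blank rule.
- Control means are per plate per day from (by default) 3 wells; their
  sampling error is the largest contributor to day-to-day wobble of
  deep-decline points. Plates designed for precision quantification
  should carry more control wells.
- The hit rule is intentionally conservative (15 pp, two consecutive
  days); subtle lifespan effects below that are reported as no_effect,
  which is the intended screening behaviour, not a power claim.
- 384-well geometry is representable in the data model but the parsers
  and simulator target 96-well plates.
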