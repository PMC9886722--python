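"""The PICLS survival statistic, outgrowth comparator, and curve assembly."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picls.errors import (
    BelowRangeError,
    InsufficientDataError,
    InvalidAnchorError,
    InvalidPlateError,
)
from picls.plate_io import Condition, ControlSummary, Role
from picls.simulate import (
    Arm,
    MeasurementModel,
    MortalityModel,
    ScreenDesign,
    simulate_outgrowth,
    simulate_plate,
    viability,
)
from picls.survival import (
    SurvivalCurve,
    SurvivalPoint,
    build_survival_curve,
    curve_summaries,
    outgrowth_survival,
    picls_survival,
)

from conftest import make_well


class TestPiclsSurvival:
    def test_boiled_control_signal_is_zero_percent(self, clean_controls):
        # a well as bright (per OD) as the dead control is 0% alive
        got = picls_survival(1050.0, 1.0, clean_controls)
        assert got.raw == pytest.approx(0.0)
        assert got.pct == 0.0

    def test_unstained_control_signal_is_hundred_percent(self, clean_controls):
        got = picls_survival(50.0, 1.0, clean_controls)
        assert got.raw == pytest.approx(100.0)

    def test_midpoint_of_controls_is_fifty_percent(self, clean_controls):
        got = picls_survival(550.0, 1.0, clean_controls)
        assert got.raw == pytest.approx(50.0)
        assert not got.clamped

    def test_below_od_floor_rejected(self, clean_controls):
        with pytest.raises(BelowRangeError):
            picls_survival(100.0, 0.04, clean_controls)

    def test_inverted_controls_rejected(self):
        bad = ControlSummary(i_c=1050.0, od_c=1.0, i_d=50.0, od_d=1.0,
                             n_neg=3, n_pos=3)
        with pytest.raises(InvalidPlateError):
            picls_survival(500.0, 1.0, bad)

    def test_clamping_keeps_raw_value_and_flags(self, clean_controls):
        over = picls_survival(40.0, 1.0, clean_controls)  # dimmer than neg
        assert over.raw > 100.0 and over.pct == 100.0 and over.clamped

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6),
           st.floats(60.0, 1040.0))
    def test_scale_invariance(self, c, d, i_well):
        """Rescaling all fluorescences by c and all ODs by d is a no-op."""
        base = ControlSummary(i_c=50.0, od_c=1.0, i_d=1050.0, od_d=1.0,
                              n_neg=3, n_pos=3)
        scaled = ControlSummary(i_c=50.0 * c, od_c=d, i_d=1050.0 * c,
                                od_d=d, n_neg=3, n_pos=3)
        a = picls_survival(i_well, 1.0, base)
        b = picls_survival(i_well * c, d, scaled, od_floor=0.0)
        assert b.raw == pytest.approx(a.raw, abs=1e-12, rel=1e-12)

    def test_strictly_decreasing_in_fluorescence(self, clean_controls):
        vals = [picls_survival(i, 1.0, clean_controls).raw
                for i in np.linspace(50, 1050, 25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestOutgrowthSurvival:
    def test_day_one_anchor_is_definitionally_hundred(self):
        assert outgrowth_survival(0.83, 0.83).pct == pytest.approx(100.0)

    def test_half_regrowth_is_fifty(self):
        assert outgrowth_survival(0.4, 0.8).pct == pytest.approx(50.0)

    def test_over_anchor_clamped_with_flag(self):
        got = outgrowth_survival(1.2, 1.0)
        assert got.pct == 100.0 and got.raw == pytest.approx(120.0) and got.clamped

    def test_nonpositive_anchor_invalid(self):
        with pytest.raises(InvalidAnchorError):
            outgrowth_survival(0.5, 0.0)


def curve_from(cond, days_values, n=6):
    pts = tuple(
        SurvivalPoint(cond, d, v, v, 0.0, n, "picls", (v,) * n)
        for d, v in days_values
    )
    return SurvivalCurve(condition=cond, points=pts)


class TestBuildSurvivalCurve:
    def test_identical_wells_have_zero_sd(self, control_plate_records):
        curves = build_survival_curve(control_plate_records)
        (curve,) = curves.values()
        pt = curve.point_at(1)
        assert pt.survival_pct == pytest.approx(50.0)
        assert pt.sd_pct == 0.0 and pt.n_wells == 3

    def test_law_of_large_numbers_against_closed_form(self):
        """At 200 wells/day (and proportionally many control wells) the
        pipeline mean converges to the generator's closed-form V(t)."""
        m = MortalityModel(k=1.3, lam=4.0)
        design = ScreenDesign(arms=(Arm(None, None, None, m),),
                              age_days=(1, 4, 7), n_replicates=200,
                              n_neg_controls=24, n_pos_controls=24)
        recs, _ = simulate_plate(design, MeasurementModel(cv=0.05), seed=2)
        curves = build_survival_curve(recs)
        curve = curves[Condition(None, None, None)]
        for day in (1, 4, 7):
            expected = 100.0 * float(viability(m, day))
            assert curve.point_at(day).survival_pct == pytest.approx(
                min(expected, 100.0), abs=2.0)

    def test_noiseless_pipeline_equals_viability_exactly(self):
        m = MortalityModel(k=1.3, lam=4.0)
        design = ScreenDesign(arms=(Arm(None, None, None, m),),
                              n_replicates=3)
        recs, _ = simulate_plate(design, MeasurementModel(cv=0.0), seed=0)
        curve = build_survival_curve(recs)[Condition(None, None, None)]
        for day in design.age_days:
            assert curve.point_at(day).survival_pct == pytest.approx(
                100.0 * float(viability(m, day)), abs=1e-9)

    def test_missing_anchor_day_rejected(self):
        recs = [make_well(well=f"A{c}", role=Role.neg_control_unstained,
                          fluor=50.0, od=1.0, day=4) for c in (1, 2, 3)]
        recs += [make_well(well=f"B{c}", role=Role.pos_control_boiled,
                           fluor=1050.0, od=1.0, day=4) for c in (1, 2, 3)]
        recs += [make_well(well=f"C{c}", role=Role.sample, compound="x",
                           conc=1.0, unit="mM", fluor=550.0, od=1.0, day=4)
                 for c in (1, 2, 3)]
        with pytest.raises(InvalidAnchorError):
            build_survival_curve(recs)

    def test_missing_controls_for_a_day_rejected(self, control_plate_records):
        day4 = [make_well(well=f"C{c}", role=Role.sample, compound="drugA",
                          conc=1.0, unit="mM", fluor=700.0, od=1.0, day=4)
                for c in (1, 2, 3)]
        with pytest.raises(InvalidPlateError):
            build_survival_curve(control_plate_records + day4)

    def test_below_floor_wells_are_excluded_not_zeroed(self, control_plate_records):
        low = make_well(well="D1", role=Role.sample, compound="drugA",
                        conc=1.0, unit="mM", fluor=550.0, od=0.01)
        curves = build_survival_curve(control_plate_records + [low])
        (curve,) = curves.values()
        assert curve.point_at(1).n_wells == 3

    def test_outgrowth_curve_tracks_viability(self):
        m = MortalityModel(k=1.3, lam=4.0)
        design = ScreenDesign(arms=(Arm(None, None, None, m),),
                              age_days=(1, 4, 7), n_replicates=6)
        recs = simulate_outgrowth(design, MeasurementModel(cv=0.0), seed=0)
        curve = build_survival_curve(recs, method="outgrowth_liquid")[
            Condition(None, None, None)]
        assert curve.point_at(1).survival_pct == pytest.approx(100.0)
        assert curve.point_at(4).survival_pct == pytest.approx(
            100.0 * float(viability(m, 4)), abs=1e-9)


class TestCurveSummaries:
    def test_constant_curve_rectangle_auc_and_censored_t50(self):
        cond = Condition("x", 1.0, "mM")
        curve = curve_from(cond, [(d, 100.0) for d in (1, 4, 7, 14, 21)])
        s = curve_summaries(curve)
        assert s.auc == pytest.approx(2000.0)
        assert s.t50_censored and s.t50 == 21.0

    def test_midpoint_interpolation(self):
        cond = Condition("x", 1.0, "mM")
        curve = curve_from(cond, [(1, 100.0), (3, 0.0)])
        assert curve_summaries(curve).t50 == pytest.approx(2.0)

    def test_t50_matches_closed_form_weibull_median(self):
        m = MortalityModel(k=1.3, lam=4.0)
        cond = Condition(None, None, None)
        curve = curve_from(cond, [(d, 100.0 * float(viability(m, d)))
                                  for d in (1, 4, 7, 14, 21)])
        median = 1.0 + m.lam * np.log(2.0) ** (1.0 / m.k)
        assert curve_summaries(curve).t50 == pytest.approx(median, abs=0.1)

    def test_single_day_curve_insufficient(self):
        cond = Condition("x", 1.0, "mM")
        curve = curve_from(cond, [(1, 100.0)])
        with pytest.raises(InsufficientDataError):
            curve_summaries(curve)
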