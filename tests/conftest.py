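import pytest

from picls.plate_io import ControlSummary, Role, WellRecord
from picls.simulate import Arm, MeasurementModel, MortalityModel, ScreenDesign


@pytest.fixture
def clean_controls():
    """Idealized control summary: I_c=50, OD_c=1, I_D=1050, OD_D=1."""
    return ControlSummary(i_c=50.0, od_c=1.0, i_d=1050.0, od_d=1.0,
                          n_neg=3, n_pos=3)


@pytest.fixture
def noiseless_measurement():
    return MeasurementModel(cv=0.0)


@pytest.fixture
def default_measurement():
    return MeasurementModel(cv=0.05)


@pytest.fixture
def control_mortality():
    return MortalityModel(k=1.3, lam=4.0)


@pytest.fixture
def two_arm_design(control_mortality):
    """Untreated control plus a long-lived arm, days 1/4/7, triplicates."""
    return ScreenDesign(
        arms=(
            Arm(None, None, None, control_mortality),
            Arm("rapamycin", 5.0, "nM", MortalityModel(k=1.3, lam=13.0)),
        ),
        age_days=(1, 4, 7),
        n_replicates=3,
    )


def make_well(plate="P1", well="A1", role=Role.sample, compound=None,
              conc=None, unit=None, day=1, rep=1, fluor=100.0, od=1.0):
    return WellRecord(plate_id=plate, well=well, role=role, compound=compound,
                      concentration=conc, concentration_unit=unit,
                      age_day=day, replicate=rep, fluorescence=fluor, od600=od)


@pytest.fixture
def control_plate_records():
    """One plate, one day: 3 neg + 3 pos controls + 3 half-dead samples."""
    recs = []
    for i, col in enumerate((1, 2, 3)):
        recs.append(make_well(well=f"A{col}", role=Role.neg_control_unstained,
                              fluor=50.0, od=1.0))
        recs.append(make_well(well=f"B{col}", role=Role.pos_control_boiled,
                              fluor=1050.0, od=1.0))
        recs.append(make_well(well=f"C{col}", role=Role.sample,
                              compound="drugA", conc=1.0, unit="mM",
                              rep=i + 1, fluor=550.0, od=1.0))
    return recs
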