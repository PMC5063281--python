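import numpy as np
import pytest

from dmdwalk import SimConfig, VisitRecord, build_intervals, simulate_cohort


def make_visit(
    patient_id="P0",
    age=9.0,
    date_offset=0,
    height=125.0,
    weight=31.25,
    six_mwd=350.0,
    rise=(4.4, True),
    mwr=(5.2, True),
    sc=(2.8, True),
    steroid_duration=2.0,
    genotype="deletion",
):
    """Hand-built clinic visit for unit tests."""
    return VisitRecord(
        patient_id=patient_id,
        age=age,
        date_offset=date_offset,
        height=height,
        weight=weight,
        six_mwd=six_mwd,
        tft_rise_time=rise[0],
        tft_rise_able=rise[1],
        tft_10mwr_time=mwr[0],
        tft_10mwr_able=mwr[1],
        tft_4sc_time=sc[0],
        tft_4sc_able=sc[1],
        steroid_duration=steroid_duration,
        genotype=genotype,
    )


@pytest.fixture(scope="session")
def mech_cohort():
    """Medium mechanistic cohort shared across read-only tests."""
    visits, truth = simulate_cohort(SimConfig(n_patients=150, seed=11))
    return visits, truth


@pytest.fixture(scope="session")
def mech_intervals(mech_cohort):
    visits, _ = mech_cohort
    return build_intervals(visits)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
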