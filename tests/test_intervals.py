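"""Interval construction: window rules, annualization, brute-force oracle."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmdwalk import WindowPolicy, annualized_change, build_intervals
from dmdwalk.errors import DataIntegrityError

from conftest import make_visit

MONTH = 30.4375


def visits_at_months(months, **kwargs):
    return [
        make_visit(date_offset=int(round(m * MONTH)), age=9.0 + m / 12.0, **kwargs)
        for m in months
    ]


def test_worked_window_example():
    """Visits at months {0, 9, 12, 24} yield exactly the 4 pairs inside 8-16
    months: 0->9, 0->12, 9->24, 12->24."""
    ivs = build_intervals(visits_at_months([0, 9, 12, 24]))
    got = {
        (round(iv.baseline_visit.date_offset / MONTH), round(iv.followup_visit.date_offset / MONTH))
        for iv in ivs
    }
    assert got == {(0, 9), (0, 12), (9, 24), (12, 24)}


def test_nonambulant_baseline_excluded():
    visits = visits_at_months([0, 12])
    visits[0] = dataclasses.replace(
        visits[0], six_mwd=0.0, tft_rise_time=None, tft_rise_able=False
    )
    assert build_intervals(visits) == []


def test_missing_baseline_field_excluded():
    visits = visits_at_months([0, 12, 24])
    visits[0] = dataclasses.replace(visits[0], height=float("nan"))
    ivs = build_intervals(visits)
    # 0->12 dropped for the missing height; 12->24 survives
    assert [(iv.baseline_visit.date_offset) for iv in ivs] == [visits[1].date_offset]


def test_duplicate_timestamps_rejected():
    visits = visits_at_months([0, 0, 12])
    with pytest.raises(DataIntegrityError, match="duplicate"):
        build_intervals(visits)


def test_empty_input():
    assert build_intervals([]) == []


def test_annualized_change_values():
    assert annualized_change(300.0, 250.0, 365.25) == pytest.approx(-50.0)
    assert annualized_change(320.0, 0.0, 365.25) == pytest.approx(-320.0)
    assert annualized_change(350.0, 280.0, 456.0) == pytest.approx(-56.07, abs=0.005)
    with pytest.raises(ValueError):
        annualized_change(300.0, 250.0, 0.0)


def test_antisymmetry_over_exact_year():
    a = build_intervals(visits_at_months([0, 12]))[0]
    swapped = visits_at_months([0, 12])
    swapped[0] = dataclasses.replace(swapped[0], six_mwd=swapped[1].six_mwd)
    swapped[1] = dataclasses.replace(swapped[1], six_mwd=350.0)
    b = build_intervals(swapped)[0]
    assert a.delta6mwd == pytest.approx(-b.delta6mwd)


def _brute_force(visits, policy):
    """Independent oracle: test every ordered same-patient pair directly."""
    out = set()
    for base in visits:
        for fup in visits:
            if base.patient_id != fup.patient_id:
                continue
            if fup.date_offset <= base.date_offset:
                continue
            if base.six_mwd <= 0:
                continue
            if any(
                getattr(base, f) != getattr(base, f) or getattr(base, f) is None
                for f in policy.required_baseline_fields
            ):
                continue
            months = (fup.date_offset - base.date_offset) / policy.days_per_month
            if policy.min_months <= months <= policy.max_months:
                out.add((base.patient_id, base.date_offset, fup.date_offset))
    return out


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=3),  # patient index
            st.integers(min_value=0, max_value=1500),  # day offset
            st.floats(min_value=0.0, max_value=500.0),  # 6MWD
        ),
        min_size=0,
        max_size=25,
    )
)
def test_matches_brute_force_oracle(raw):
    seen = set()
    visits = []
    for pid, day, walk in raw:
        if (pid, day) in seen:
            continue
        seen.add((pid, day))
        visits.append(
            make_visit(patient_id=f"P{pid}", date_offset=day, age=5.0 + day / 365.25, six_mwd=walk)
        )
    policy = WindowPolicy()
    got = {
        (iv.patient_id, iv.baseline_visit.date_offset, iv.followup_visit.date_offset)
        for iv in build_intervals(visits, policy)
    }
    assert got == _brute_force(visits, policy)


def test_interval_count_bound(mech_intervals):
    per_patient = {}
    per_visits = {}
    for iv in mech_intervals:
        per_patient[iv.patient_id] = per_patient.get(iv.patient_id, 0) + 1
        per_visits.setdefault(iv.patient_id, set()).update(
            {iv.baseline_visit.date_offset, iv.followup_visit.date_offset}
        )
    for pid, count in per_patient.items():
        v = len(per_visits[pid])
        assert count <= v * (v - 1) / 2


def test_interval_invariants(mech_intervals):
    for iv in mech_intervals:
        assert iv.baseline_visit.six_mwd > 0
        months = iv.elapsed_days / 30.4375
        assert 8.0 <= months <= 16.0
        expected = (iv.followup_visit.six_mwd - iv.baseline_visit.six_mwd) / iv.elapsed_years
        assert iv.delta6mwd == pytest.approx(expected, rel=1e-12)
        if iv.lost_ambulation:
            assert iv.delta6mwd < 0
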