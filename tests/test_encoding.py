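"""Covariate encoding: two-part TFTs, cap rule, transforms, model matrices."""

import numpy as np
import pytest

from dmdwalk import (
    MODEL1,
    MODEL2,
    MODEL3,
    ModelSpec,
    build_intervals,
    cap_tft_for_correlation,
    encode_model_matrix,
    encode_tft,
    transform_tft,
)
from dmdwalk.errors import DataIntegrityError, SchemaError

from conftest import make_visit


def two_visit_intervals(**base_kwargs):
    base = make_visit(date_offset=0, **base_kwargs)
    fup = make_visit(date_offset=365, age=base.age + 1.0, six_mwd=base.six_mwd - 40)
    return build_intervals([base, fup])


@pytest.mark.parametrize(
    "time, able, expected",
    [
        (None, False, (0, 0.0)),
        (4.4, True, (1, 4.4)),
        (0.0, True, (1, 0.0)),
    ],
)
def test_encode_tft(time, able, expected):
    assert encode_tft(time, able) == expected


def test_encode_tft_inconsistency():
    with pytest.raises(DataIntegrityError):
        encode_tft(None, True)


@pytest.mark.parametrize(
    "time, able, expected",
    [(None, False, 30.0), (5.2, True, 5.2), (40.0, True, 30.0)],
)
def test_cap_rule(time, able, expected):
    assert cap_tft_for_correlation(time, able) == expected


def test_cap_rejects_negative():
    with pytest.raises(ValueError):
        cap_tft_for_correlation(-1.0, True)


@pytest.mark.parametrize(
    "args, expected",
    [
        (((5.0, True), "velocity", "10mwr"), 2.0),
        (((None, False), "velocity", "rise"), 0.0),
        (((4.0, True), "threshold", "rise", 5.0), 1.0),
        (((6.0, True), "threshold", "rise", 5.0), 0.0),
        (((4.0, True), "reciprocal", "4sc"), 0.25),
    ],
)
def test_transform_tft(args, expected):
    (time, able), kind, test, *cut = args
    cutoff = cut[0] if cut else None
    assert transform_tft(time, able, kind, test, cutoff=cutoff) == expected


def test_transform_rejects_zero_time():
    with pytest.raises(ValueError):
        transform_tft(0.0, True, "velocity", "10mwr")


def test_model1_columns():
    ivs = two_visit_intervals()
    design = encode_model_matrix(ivs, MODEL1)
    assert design.column_names == ["intercept", "age", "steroid_ge1yr", "baseline_6mwd"]
    np.testing.assert_allclose(design.values[0], [1.0, 9.0, 1.0, 350.0])
    assert design.outcome[0] == pytest.approx(-40.0 * 365.25 / 365.0)


def test_bmi_and_steroid_threshold():
    low = two_visit_intervals(height=125.0, weight=31.25, steroid_duration=0.5)
    hi = two_visit_intervals(steroid_duration=2.8)
    d_low = encode_model_matrix(low, MODEL2)
    d_hi = encode_model_matrix(hi, MODEL2)
    bmi = d_low.values[0][d_low.column_names.index("bmi")]
    assert bmi == pytest.approx(20.0)
    i = d_low.column_names.index("steroid_ge1yr")
    assert d_low.values[0][i] == 0.0 and d_hi.values[0][i] == 1.0


def test_constant_ability_columns_dropped(mech_intervals):
    design = encode_model_matrix(mech_intervals, MODEL2)
    # the 10 m walk/run has no ability term in the broad model by construction
    assert "tft_able_10mwr" not in design.column_names
    for name in design.dropped_columns:
        assert name.startswith(("tft_able_", "genotype_"))


def test_genotype_dummies(mech_intervals):
    design = encode_model_matrix(mech_intervals, MODEL3)
    cols = [c for c in design.column_names if c.startswith("genotype_")]
    assert "genotype_duplication" in cols  # deletion is the reference class
    values = design.values[:, [design.column_names.index(c) for c in cols]]
    assert set(np.unique(values)) <= {0.0, 1.0}
    assert values.sum(axis=1).max() <= 1.0


def test_row_permutation_equivariance(mech_intervals):
    ivs = list(mech_intervals)[:60]
    design = encode_model_matrix(ivs, MODEL2)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ivs))
    permuted = encode_model_matrix([ivs[i] for i in perm], MODEL2)
    np.testing.assert_array_equal(permuted.values, design.values[perm])
    np.testing.assert_array_equal(permuted.outcome, design.outcome[perm])
    np.testing.assert_array_equal(permuted.cluster_ids, design.cluster_ids[perm])


def test_two_part_identifiability(mech_intervals):
    design = encode_model_matrix(mech_intervals, MODEL2)
    cols = design.column_names
    for test in ("rise", "4sc"):
        if f"tft_able_{test}" not in cols:
            continue
        able = design.values[:, cols.index(f"tft_able_{test}")]
        time = design.values[:, cols.index(f"tft_time_{test}")]
        np.testing.assert_array_equal(able, (time > 0).astype(float))


def test_modelspec_validation():
    with pytest.raises(SchemaError, match="intercept"):
        ModelSpec("bad", ("age",))
    with pytest.raises(SchemaError, match="duplicate"):
        ModelSpec("bad", ("intercept", "age", "age"))
    with pytest.raises(SchemaError, match="unknown"):
        ModelSpec("bad", ("intercept", "flux_capacitor"))
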