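"""RMSE/R² metrics, patient-level cross-validation, bootstrap-of-CV."""

import numpy as np
import pytest

from dmdwalk import (
    MODEL1,
    ModelSpec,
    SimConfig,
    bootstrap_cv_ci,
    build_intervals,
    cross_validate,
    evaluate,
    simulate_linear_mode,
)
from dmdwalk.errors import DegenerateOutcomeError, SchemaError

LIN_SPEC = ModelSpec("lin", ("intercept", "age", "baseline_6mwd"))
LIN_BETA = {"intercept": 30.0, "age": -8.0, "baseline_6mwd": 0.05}


def linear_intervals(n_patients, residual_sd, random_effect_sd, seed):
    visits, _ = simulate_linear_mode(
        SimConfig(n_patients=n_patients, seed=seed), LIN_BETA, random_effect_sd, residual_sd
    )
    return build_intervals(visits)


def test_perfect_prediction():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    res = evaluate(obs, obs)
    assert res.rmse == 0.0 and res.r2 == 1.0


def test_published_identity_triplet():
    """The printed RMSE/SD pairs reproduce the printed R² values."""
    obs = np.array([0.0, 93.7 * np.sqrt(2.0)])  # two points with SD exactly 93.7
    for rmse, r2 in [(79.4, 0.28), (59.7, 0.59), (51.7, 0.70)]:
        pred = obs + np.array([-1.0, 1.0]) * rmse / np.sqrt(2.0)
        ev = evaluate(obs, pred)
        assert ev.sd_observed == pytest.approx(93.7)
        assert ev.rmse == pytest.approx(rmse, rel=1e-12)
        assert round(ev.r2, 2) == r2


def test_eval_errors():
    with pytest.raises(SchemaError):
        evaluate(np.ones(3), np.ones(4))
    with pytest.raises(DegenerateOutcomeError):
        evaluate(np.ones(5), np.zeros(5))


def test_rmse_methods_differ_off_center():
    obs = np.array([0.0, 1.0, 2.0, 3.0])
    pred = obs - 10.0  # constant bias: SD of residuals ignores it, RMS does not
    sd_based = evaluate(obs, pred, method="sd_of_residuals")
    rms_based = evaluate(obs, pred, method="rms_of_residuals")
    assert sd_based.rmse < rms_based.rmse
    # identity r2 = 1 - (rmse/sd)^2 holds for both
    for ev in (sd_based, rms_based):
        assert ev.r2 == pytest.approx(1 - (ev.rmse / ev.sd_observed) ** 2, abs=1e-12)


def test_split_sizes_31_of_39():
    import math

    assert math.floor(0.8 * 39) == 31  # 31 train / 8 evaluation patients


def test_cv_noiseless_perfect_model():
    ivs = linear_intervals(25, 0.0, 0.0, seed=2)
    cv = cross_validate(ivs, LIN_SPEC, n_splits=20, seed=0)
    assert cv.mean_rmse < 1e-6
    assert cv.split_unit == "patient"


def test_cv_estimates_irreducible_noise():
    """With independent noise of SD 60 and a correct mean model, CV RMSE
    estimates 60 m."""
    ivs = linear_intervals(200, 60.0, 0.0, seed=8)
    cv = cross_validate(ivs, LIN_SPEC, n_splits=60, seed=1)
    assert cv.mean_rmse == pytest.approx(60.0, abs=5.0)
    assert cv.derived_r2 == pytest.approx(1 - (cv.mean_rmse / np.std([iv.delta6mwd for iv in ivs], ddof=1)) ** 2, abs=1e-9)


def test_cv_determinism(mech_intervals):
    a = cross_validate(mech_intervals, MODEL1, n_splits=25, seed=5)
    b = cross_validate(mech_intervals, MODEL1, n_splits=25, seed=5)
    assert a.per_split_rmse == b.per_split_rmse


def test_cv_optimism_direction():
    """Held-out RMSE of the broad model exceeds its in-sample RMSE in nearly
    every replicate cohort (cross-validation is the conservative estimate)."""
    from dmdwalk import MODEL2, ExchangeableGEE, simulate_cohort
    from dmdwalk import evaluate as ev

    wins = 0
    n_rep = 20
    for s in range(n_rep):
        visits, _ = simulate_cohort(SimConfig(n_patients=60, seed=100 + s))
        ivs = build_intervals(visits)
        res = ExchangeableGEE.from_intervals(ivs, MODEL2).fit()
        in_sample = ev(res.model.endog, res.predict()).rmse
        cv = cross_validate(ivs, MODEL2, n_splits=20, seed=s).mean_rmse
        wins += cv >= in_sample
    assert wins >= 0.9 * n_rep


def test_cv_requires_enough_patients():
    ivs = linear_intervals(3, 10.0, 0.0, seed=0)
    with pytest.raises(SchemaError, match="5 patients"):
        cross_validate(ivs, LIN_SPEC)


def test_noise_columns_do_not_improve_in_sample_fit(mech_intervals):
    """Adding pure-noise columns cannot worsen, and barely changes, the
    in-sample least-squares picture; CV shows no systematic gain."""
    from dmdwalk import ExchangeableGEE, encode_model_matrix
    from dmdwalk.evaluation import evaluate as ev

    design = encode_model_matrix(mech_intervals, MODEL1)
    rng = np.random.default_rng(0)
    X_noise = np.column_stack([design.values, rng.normal(size=design.n_rows)])
    base = ExchangeableGEE(design.outcome, design.values, design.cluster_ids).fit()
    noisy = ExchangeableGEE(design.outcome, X_noise, design.cluster_ids).fit()
    r_base = ev(design.outcome, base.predict()).rmse
    r_noisy = ev(design.outcome, noisy.predict(X_noise)).rmse
    assert r_noisy <= r_base + 0.5


def test_bootstrap_noiseless_degenerate():
    ivs = linear_intervals(20, 0.0, 0.0, seed=4)
    ci = bootstrap_cv_ci(ivs, LIN_SPEC, n_boot=25, n_splits_inner=8, seed=0)
    assert ci.lower == pytest.approx(0.0, abs=1e-6)
    assert ci.upper == pytest.approx(0.0, abs=1e-6)


def test_bootstrap_determinism():
    ivs = linear_intervals(20, 30.0, 10.0, seed=4)
    a = bootstrap_cv_ci(ivs, LIN_SPEC, n_boot=15, n_splits_inner=6, seed=9)
    b = bootstrap_cv_ci(ivs, LIN_SPEC, n_boot=15, n_splits_inner=6, seed=9)
    assert (a.lower, a.point, a.upper) == (b.lower, b.point, b.upper)
    assert a.lower <= a.point <= a.upper
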