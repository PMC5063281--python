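"""Synthetic natural-history cohorts for ambulatory decline in DMD.

The generator produces visit-level records mimicking a routine-care clinic:
boys assessed roughly every six months with six-minute walk distance (6MWD),
three timed function tests (TFTs), anthropometrics, steroid history and a
dystrophin genotype class.  Two modes are provided:

* ``simulate_cohort`` — mechanistic trajectories.  Each patient carries a
  latent ambulatory function that plateaus at a personal peak around age 7 and
  declines quadratically thereafter, reaching 0 at loss of ambulation.  All
  observed measures (6MWD, TFT times, ability flags) derive from this latent
  function, which induces the strong cross-correlations seen in natural
  history data.

* ``simulate_linear_mode`` — the annualized outcome is generated from a known
  linear model Δ6MWD = Xβ + bᵢ + ε on top of mechanistically drawn baseline
  covariates.  Used for parameter-recovery and coverage experiments where the
  ground truth must be exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "SimConfig",
    "VisitRecord",
    "TruthRecord",
    "GENOTYPE_CLASSES",
    "TFT_TESTS",
    "LINEAR_COVARIATES",
    "simulate_cohort",
    "simulate_linear_mode",
]

GENOTYPE_CLASSES = ("deletion", "duplication", "point mutation", "other")
TFT_TESTS = ("rise", "10mwr", "4sc")

#: Covariate names accepted by the linear generating model; these match the
#: design-matrix column names produced by :mod:`dmdwalk.design`.
LINEAR_COVARIATES = (
    "intercept",
    "age",
    "steroid_ge1yr",
    "baseline_6mwd",
    "height",
    "weight",
    "bmi",
    "tft_time_rise",
    "tft_able_rise",
    "tft_time_10mwr",
    "tft_able_10mwr",
    "tft_time_4sc",
    "tft_able_4sc",
    "genotype_duplication",
    "genotype_point mutation",
    "genotype_other",
)


@dataclass(frozen=True)
class TFTLink:
    """Maps the latent ambulatory score (6MWD metres) to one timed test.

    ``time = median_s * exp(gain * (350 - score)/300) * exp(noise)`` for
    ambulant patients above ``able_threshold``; below the threshold the test
    cannot be completed.  Parameters are anchored so that a typical ambulant
    boy (score ~350 m) produces the observed median time and a boy close to
    loss of ambulation approaches the longest observed completion times.
    """

    median_s: float
    gain: float
    able_threshold: float  # latent score below which the test fails
    noise_sd: float = 0.15  # log-scale measurement noise


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the mechanistic cohort generator.

    Defaults are calibrated so that a large simulated cohort matches the
    published natural-history profile of ambulant DMD boys: baseline 6MWD
    ~352 m (SD ~80), mean annualized change ~ -37 m/year (SD ~94), and
    ~12-13% of 1-year intervals ending in loss of ambulation.
    """

    n_patients: int = 39
    entry_age_range: tuple[float, float] = (4.4, 11.5)  # years
    visit_spacing_mean: float = 6.0  # months
    visit_spacing_jitter: float = 1.0  # months (SD)
    followup_span_range: tuple[float, float] = (2.0, 5.0)  # years
    peak_age_mean: float = 7.0  # years
    peak_age_sd: float = 1.2
    peak_6mwd_mean: float = 410.0  # m
    peak_6mwd_sd: float = 50.0
    decline_rate_mean: float = 12.0  # m/year^2 curvature of post-peak decline
    decline_rate_sd: float = 14.0  # lognormal across patients (heavy right tail)
    rise_rate_mean: float = 8.0  # m/year^2 curvature of the childhood rise
    rise_rate_sd: float = 3.0
    loss_threshold_range: tuple[float, float] = (50.0, 300.0)  # m, per-patient reserve
    measurement_noise_sd: float = 22.0  # m; respects 6MWD test-retest r > 0.9
    tft_links: dict = field(
        default_factory=lambda: {
            "rise": TFTLink(median_s=5.0, gain=1.7, able_threshold=250.0),
            "10mwr": TFTLink(median_s=5.5, gain=1.05, able_threshold=0.0),
            "4sc": TFTLink(median_s=3.3, gain=2.0, able_threshold=180.0),
        }
    )
    tft_lead_years: float = 1.0  # TFTs track the latent function this far ahead
    steroid_start_age_mean: float = 6.0  # years
    steroid_start_age_sd: float = 1.5
    genotype_class_probs: tuple[float, float, float, float] = (0.733, 0.188, 0.079, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("visit_spacing_mean", "measurement_noise_sd"):
            if getattr(self, name) < 0 or (name == "visit_spacing_mean" and getattr(self, name) <= 0):
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("entry_age_range", "followup_span_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must satisfy 0 < low < high, got {(lo, hi)}")
        probs = np.asarray(self.genotype_class_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "genotype_class_probs must be non-negative and sum to 1 "
                f"(got sum {probs.sum()!r})"
            )
        if self.peak_6mwd_mean <= 0 or self.decline_rate_mean <= 0:
            raise ConfigError("peak_6mwd_mean and decline_rate_mean must be strictly positive")


@dataclass
class VisitRecord:
    """One clinic assessment of one patient."""

    patient_id: str
    age: float  # years
    date_offset: int  # days since the patient's first visit
    height: float  # cm
    weight: float  # kg
    six_mwd: float  # m; 0 encodes inability to complete (loss of ambulation)
    tft_rise_time: Optional[float]  # seconds, None when unable
    tft_rise_able: bool
    tft_10mwr_time: Optional[float]
    tft_10mwr_able: bool
    tft_4sc_time: Optional[float]
    tft_4sc_able: bool
    steroid_duration: float  # years of prior steroid use, 0 if never
    genotype: str  # one of GENOTYPE_CLASSES

    def tft(self, test: str) -> tuple[Optional[float], bool]:
        """Return the (time, able) pair for one timed function test."""
        return (
            getattr(self, f"tft_{test}_time"),
            getattr(self, f"tft_{test}_able"),
        )


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery tests."""

    mode: str  # "mechanistic" or "linear"
    true_beta: Optional[dict[str, float]]  # linear mode only
    patient_random_effect_sd: float  # m
    residual_sd: float  # m
    n_clamped_outcomes: int = 0  # linear-mode follow-ups floored at 6MWD = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# patient-level latent machinery


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # Stable per-patient substream: reordering patients cannot change any
    # individual trajectory.
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), int(index))))


@dataclass
class _PatientLatent:
    peak: float
    peak_age: float
    decline_rate: float
    rise_rate: float
    loss_threshold: float  # m; ambulation collapses once the decline crosses this
    height_intercept: float
    height_slope: float
    weight_intercept: float
    weight_slope: float
    steroid_start_age: float
    genotype: str

    def score(self, age: float) -> float:
        """Latent ambulatory function in 6MWD metres; 0 = ambulation lost.

        Quadratic rise toward a personal peak near age ~7, then quadratic
        decline, so losses accelerate with age.
        """
        if age < self.peak_age:
            gap = self.peak_age - age
            return max(0.0, self.peak - self.rise_rate * gap * gap)
        excess = age - self.peak_age
        value = self.peak - self.decline_rate * excess * excess
        # ambulation is lost abruptly: once the declining limb falls below a
        # patient-specific reserve, the walk test can no longer be completed
        if value <= self.loss_threshold:
            return 0.0
        return value


def _lognormal_from_moments(rng: np.random.Generator, mean: float, sd: float) -> float:
    # heavy right tail: a minority of fast decliners drives loss of ambulation
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw_patient(config: SimConfig, rng: np.random.Generator) -> _PatientLatent:
    peak = max(150.0, rng.normal(config.peak_6mwd_mean, config.peak_6mwd_sd))
    peak_age = max(4.0, rng.normal(config.peak_age_mean, config.peak_age_sd))
    rate = _lognormal_from_moments(rng, config.decline_rate_mean, config.decline_rate_sd)
    genotype = GENOTYPE_CLASSES[
        rng.choice(len(GENOTYPE_CLASSES), p=np.asarray(config.genotype_class_probs, float))
    ]
    return _PatientLatent(
        peak=peak,
        peak_age=peak_age,
        decline_rate=rate,
        rise_rate=max(0.5, rng.normal(config.rise_rate_mean, config.rise_rate_sd)),
        loss_threshold=rng.uniform(*config.loss_threshold_range),
        height_intercept=84.0 + rng.normal(0.0, 3.0),
        height_slope=4.2 * math.exp(rng.normal(0.0, 0.08)),
        weight_intercept=7.5 + rng.normal(0.0, 1.5),
        weight_slope=2.36 * math.exp(rng.normal(0.0, 0.18)),
        steroid_start_age=max(3.0, rng.normal(config.steroid_start_age_mean, config.steroid_start_age_sd)),
        genotype=genotype,
    )


def _measure_visit(
    config: SimConfig,
    latent: _PatientLatent,
    patient_id: str,
    age: float,
    date_offset: int,
    rng: np.random.Generator,
) -> VisitRecord:
    score = latent.score(age)
    ambulant = score > 0.0
    if ambulant:
        six_mwd = max(1.0, score + rng.normal(0.0, config.measurement_noise_sd))
    else:
        six_mwd = 0.0

    # Timed tests probe proximal strength, which fails ahead of walking
    # endurance: they track the latent function a little into the future and
    # therefore carry prognostic information beyond the concurrent 6MWD.
    tft_score = latent.score(age + config.tft_lead_years)
    tft: dict[str, tuple[Optional[float], bool]] = {}
    for test in TFT_TESTS:
        link: TFTLink = config.tft_links[test]
        if ambulant and tft_score > link.able_threshold:
            t = link.median_s * math.exp(link.gain * (350.0 - tft_score) / 300.0)
            t *= math.exp(rng.normal(0.0, link.noise_sd))
            tft[test] = (round(t, 1), True)
        else:
            tft[test] = (None, False)

    return VisitRecord(
        patient_id=patient_id,
        age=age,
        date_offset=date_offset,
        height=latent.height_intercept + latent.height_slope * age,
        weight=max(5.0, latent.weight_intercept + latent.weight_slope * age),
        six_mwd=six_mwd,
        tft_rise_time=tft["rise"][0],
        tft_rise_able=tft["rise"][1],
        tft_10mwr_time=tft["10mwr"][0],
        tft_10mwr_able=tft["10mwr"][1],
        tft_4sc_time=tft["4sc"][0],
        tft_4sc_able=tft["4sc"][1],
        steroid_duration=max(0.0, age - latent.steroid_start_age),
        genotype=latent.genotype,
    )


def simulate_cohort(config: SimConfig) -> tuple[list[VisitRecord], TruthRecord]:
    """Generate a mechanistic visit-level cohort.

    Returns the visits (sorted by patient then date) and a :class:`TruthRecord`
    documenting the noise structure.  Identical configs (including the seed)
    yield identical cohorts.
    """
    config.validate()
    visits: list[VisitRecord] = []
    for idx in range(config.n_patients):
        rng = _patient_rng(config.seed, idx)
        latent = _draw_patient(config, rng)
        pid = f"P{idx:03d}"
        lo, hi = config.entry_age_range
        entry_age = rng.uniform(lo, hi)
        span_lo, span_hi = config.followup_span_range
        span_years = rng.uniform(span_lo, span_hi)
        offset_days = 0
        while True:
            age = entry_age + offset_days / 365.25
            if age - entry_age > span_years:
                break
            visits.append(_measure_visit(config, latent, pid, age, offset_days, rng))
            gap_months = rng.normal(config.visit_spacing_mean, config.visit_spacing_jitter)
            gap_months = max(2.0, gap_months)
            offset_days += int(round(gap_months * 30.4375))
        # a patient always contributes at least two visits
        if sum(v.patient_id == pid for v in visits) < 2:
            age = entry_age + offset_days / 365.25
            visits.append(_measure_visit(config, latent, pid, age, offset_days, rng))
    truth = TruthRecord(
        mode="mechanistic",
        true_beta=None,
        patient_random_effect_sd=0.0,
        residual_sd=config.measurement_noise_sd,
    )
    return visits, truth


# ---------------------------------------------------------------------------
# linear generating mode


def _covariate_value(visit: VisitRecord, name: str) -> float:
    """Evaluate one linear-model covariate at a baseline visit."""
    if name == "intercept":
        return 1.0
    if name == "age":
        return visit.age
    if name == "steroid_ge1yr":
        return 1.0 if visit.steroid_duration >= 1.0 else 0.0
    if name == "baseline_6mwd":
        return visit.six_mwd
    if name == "height":
        return visit.height
    if name == "weight":
        return visit.weight
    if name == "bmi":
        return visit.weight / (visit.height / 100.0) ** 2
    if name.startswith("tft_time_"):
        time, able = visit.tft(name.removeprefix("tft_time_"))
        return float(time) if able else 0.0
    if name.startswith("tft_able_"):
        _, able = visit.tft(name.removeprefix("tft_able_"))
        return 1.0 if able else 0.0
    if name.startswith("genotype_"):
        return 1.0 if visit.genotype == name.removeprefix("genotype_") else 0.0
    raise KeyError(name)


def simulate_linear_mode(
    config: SimConfig,
    beta: dict[str, float],
    random_effect_sd: float,
    residual_sd: float,
) -> tuple[list[VisitRecord], TruthRecord]:
    """Generate a cohort whose annualized outcome follows a known linear model.

    Baseline covariates are drawn from the mechanistic machinery; each patient
    contributes a sequence of disjoint (baseline, ~12-month follow-up) visit
    pairs spaced so that no other pair falls inside the 8-16 month window.
    The follow-up 6MWD is then set so that, after interval construction,

        Δ6MWD = x'β + bᵢ + ε,   bᵢ ~ N(0, random_effect_sd²),
                                 ε  ~ N(0, residual_sd²).

    Follow-up walk distances that would fall below 0 are floored at 0 (and
    counted in the returned :class:`TruthRecord`); with the default covariate
    scales this is a rare tail event.
    """
    config.validate()
    bad = sorted(set(beta) - set(LINEAR_COVARIATES))
    if bad:
        raise ConfigError(
            f"unknown covariate name(s) in beta: {bad}; valid names are {list(LINEAR_COVARIATES)}"
        )
    if random_effect_sd < 0 or residual_sd < 0:
        raise ConfigError("random_effect_sd and residual_sd must be >= 0")

    pair_spacing_days = int(round(30 * 30.4375))  # 30 months between baselines
    within_pair_days = int(round(12 * 30.4375))  # ~12-month outcome window

    visits: list[VisitRecord] = []
    n_clamped = 0
    for idx in range(config.n_patients):
        rng = _patient_rng(config.seed, idx)
        latent = _draw_patient(config, rng)
        pid = f"P{idx:03d}"
        lo, hi = config.entry_age_range
        entry_age = rng.uniform(lo, hi)
        span_lo, span_hi = config.followup_span_range
        span_years = rng.uniform(span_lo, span_hi)
        n_pairs = max(1, int(math.floor((span_years * 12.0 - 12.0) / 30.0)) + 1)
        b_i = rng.normal(0.0, random_effect_sd) if random_effect_sd > 0 else 0.0
        for j in range(n_pairs):
            base_offset = j * pair_spacing_days
            base_age = entry_age + base_offset / 365.25
            base = _measure_visit(config, latent, pid, base_age, base_offset, rng)
            if base.six_mwd <= 0.0:
                # keep the baseline ambulant so the pair qualifies
                base.six_mwd = max(50.0, base.six_mwd + 300.0)
            fup_offset = base_offset + within_pair_days
            fup_age = entry_age + fup_offset / 365.25
            fup = _measure_visit(config, latent, pid, fup_age, fup_offset, rng)
            x_beta = sum(coef * _covariate_value(base, name) for name, coef in beta.items())
            eps = rng.normal(0.0, residual_sd) if residual_sd > 0 else 0.0
            delta = x_beta + b_i + eps
            elapsed_years = (fup_offset - base_offset) / 365.25
            target = base.six_mwd + delta * elapsed_years
            if target < 0.0:
                target = 0.0
                n_clamped += 1
            fup.six_mwd = target
            visits.extend([base, fup])

    truth = TruthRecord(
        mode="linear",
        true_beta=dict(beta),
        patient_random_effect_sd=float(random_effect_sd),
        residual_sd=float(residual_sd),
        n_clamped_outcomes=n_clamped,
    )
    return visits, truth
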