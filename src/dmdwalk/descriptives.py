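"""Baseline descriptives, Pearson correlation report and the variable ledger.

The correlation analysis uses the 30-second cap rule for timed tests (a
patient unable to complete a test is assigned 30 s) and continuous steroid
duration; the regression models instead use the two-part TFT encoding and the
>= 1 year steroid dichotomy.  The two conventions are deliberately distinct
and labelled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    MODEL1,
    MODEL2,
    ModelSpec,
    cap_tft_for_correlation,
    encode_model_matrix,
)
from .errors import SchemaError
from .evaluation import evaluate
from .gee import ExchangeableGEE
from .intervals import FollowUpInterval

__all__ = ["CorrelationReport", "LedgerRow", "correlation_report", "variable_ledger", "DEFAULT_CANDIDATES"]

logger = logging.getLogger(__name__)

_CORR_VARIABLES = (
    "age",
    "steroid_duration",
    "height",
    "weight",
    "bmi",
    "baseline_6mwd",
    "tft_10mwr_capped",
    "tft_rise_capped",
    "tft_4sc_capped",
    "delta6mwd",
)


@dataclass
class CorrelationReport:
    variables: tuple[str, ...]
    r: pd.DataFrame  # symmetric Pearson matrix
    p: pd.DataFrame  # two-sided p-values (t reference, n-2 df)
    n: int
    notices: list[str]


def _correlation_frame(intervals: list[FollowUpInterval], cap: float) -> pd.DataFrame:
    rows = []
    for iv in intervals:
        b = iv.baseline_visit
        rows.append(
            {
                "age": b.age,
                "steroid_duration": b.steroid_duration,
                "height": b.height,
                "weight": b.weight,
                "bmi": b.weight / (b.height / 100.0) ** 2,
                "baseline_6mwd": b.six_mwd,
                "tft_10mwr_capped": cap_tft_for_correlation(*b.tft("10mwr"), cap=cap),
                "tft_rise_capped": cap_tft_for_correlation(*b.tft("rise"), cap=cap),
                "tft_4sc_capped": cap_tft_for_correlation(*b.tft("4sc"), cap=cap),
                "delta6mwd": iv.delta6mwd,
            }
        )
    return pd.DataFrame(rows, columns=list(_CORR_VARIABLES))


def correlation_report(intervals: list[FollowUpInterval], cap: float = 30.0) -> CorrelationReport:
    """Pairwise Pearson correlations among baseline characteristics and Δ6MWD."""
    if len(intervals) < 3:
        raise SchemaError("correlation report needs at least 3 intervals")
    frame = _correlation_frame(intervals, cap)
    k = len(_CORR_VARIABLES)
    r = np.eye(k)
    p = np.zeros((k, k))
    notices: list[str] = []
    cols = [frame[v].to_numpy(float) for v in _CORR_VARIABLES]
    for i in range(k):
        if np.ptp(cols[i]) == 0.0:
            notices.append(f"{_CORR_VARIABLES[i]} is constant; correlations undefined")
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(cols[i]) == 0.0 or np.ptp(cols[j]) == 0.0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = stats.pearsonr(cols[i], cols[j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = list(_CORR_VARIABLES)
    return CorrelationReport(
        variables=_CORR_VARIABLES,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=len(intervals),
        notices=notices,
    )


@dataclass(frozen=True)
class LedgerRow:
    """One fitted model in the add/remove/isolation prognostic-value ledger."""

    label: str
    kind: str  # "add_to_model1" | "remove_from_model2" | "isolated" | "base"
    r2: float
    rmse: float  # m
    delta_r2_vs_base: float


#: Candidate variables for the ledger.  Each candidate is a named group of
#: model terms; TFTs appear both as their full two-part encoding and as a
#: time-only variant.
DEFAULT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "height": ("height",),
    "weight": ("weight",),
    "bmi": ("bmi",),
    "age": ("age",),
    "baseline_6mwd": ("baseline_6mwd",),
    "steroid_ge1yr": ("steroid_ge1yr",),
    "10mwr": ("tft_time:10mwr",),
    "rise": ("tft_able:rise", "tft_time:rise"),
    "rise (time only)": ("tft_time:rise",),
    "4sc": ("tft_able:4sc", "tft_time:4sc"),
    "4sc (time only)": ("tft_time:4sc",),
    "genotype": ("genotype",),
}


def _fit_r2(intervals: list[FollowUpInterval], spec: ModelSpec) -> tuple[float, float]:
    res = ExchangeableGEE.from_intervals(intervals, spec).fit()
    ev = evaluate(res.model.endog, res.predict())
    return ev.r2, ev.rmse


def variable_ledger(
    intervals: list[FollowUpInterval],
    base_specs: tuple[ModelSpec, ModelSpec] = (MODEL1, MODEL2),
    candidates: dict[str, tuple[str, ...]] | None = None,
) -> list[LedgerRow]:
    """Prognostic-value ledger: each candidate added to the narrow base model,
    removed from the broad base model, and fitted in isolation.

    Fits use the GEE engine throughout; because GEE weights within-patient
    correlation, in-sample R² is *not* guaranteed to grow when variables are
    added, and the ledger makes no monotonicity claim.
    """
    candidates = candidates or DEFAULT_CANDIDATES
    narrow, broad = base_specs
    rows: list[LedgerRow] = []

    r2_narrow, rmse_narrow = _fit_r2(intervals, narrow)
    r2_broad, rmse_broad = _fit_r2(intervals, broad)
    rows.append(LedgerRow(narrow.name, "base", r2_narrow, rmse_narrow, 0.0))
    rows.append(LedgerRow(broad.name, "base", r2_broad, rmse_broad, 0.0))

    for label, terms in candidates.items():
        new_terms = [t for t in terms if t not in narrow.terms]
        if new_terms:
            spec = narrow.add(*new_terms, name=f"{narrow.name} + {label}")
            r2, rmse = _fit_r2(intervals, spec)
            rows.append(LedgerRow(spec.name, "add_to_model1", r2, rmse, r2 - r2_narrow))

        gone = [t for t in terms if t in broad.terms]
        if gone:
            spec = broad.drop(*gone, name=f"{broad.name} - {label}")
            if len(spec.terms) <= 1:
                logger.warning("removing %s would empty %s; skipped", label, broad.name)
            else:
                r2, rmse = _fit_r2(intervals, spec)
                rows.append(LedgerRow(spec.name, "remove_from_model2", r2, rmse, r2 - r2_broad))

        iso = ModelSpec(f"intercept + {label}", ("intercept",) + tuple(terms))
        r2, rmse = _fit_r2(intervals, iso)
        rows.append(LedgerRow(iso.name, "isolated", r2, rmse, r2))

    rows.sort(key=lambda row: row.delta_r2_vs_base, reverse=True)
    return rows


def ledger_frame(rows: list[LedgerRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.label,
                "kind": r.kind,
                "r2": r.r2,
                "rmse_m": r.rmse,
                "delta_r2_vs_base": r.delta_r2_vs_base,
            }
            for r in rows
        ]
    )
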