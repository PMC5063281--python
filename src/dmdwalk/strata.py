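"""Quartile stratification of intervals by model-predicted Δ6MWD.

The unit of stratification is the follow-up interval (one patient can appear
in several strata across intervals).  Thresholds are the 25th/50th/75th
percentiles of the predictions (linear interpolation between order
statistics); assignment uses half-open bins [lo, hi), open below for the
lowest stratum and closed above for the highest, matching the published
boundary convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .intervals import FollowUpInterval

__all__ = ["STRATUM_LABELS", "QuartileStrata", "assign_quartiles", "stratum_summaries", "box_summary"]

STRATUM_LABELS = ("fast decline", "moderate decline", "stable", "improved")


@dataclass
class QuartileStrata:
    thresholds: tuple[float, float, float]  # m/year cut points
    labels: tuple[str, ...]
    assignment: np.ndarray  # stratum index per interval, aligned with predictions
    counts: dict[str, int]

    def label_of(self, prediction: float) -> str:
        return self.labels[_bin_index(prediction, self.thresholds)]


def _bin_index(value: float, thresholds: tuple[float, float, float]) -> int:
    t1, t2, t3 = thresholds
    if value < t1:
        return 0
    if value < t2:
        return 1
    if value < t3:
        return 2
    return 3


def assign_quartiles(
    predictions: Sequence[float],
    labels: tuple[str, ...] = STRATUM_LABELS,
) -> QuartileStrata:
    """Partition predictions into quartile strata of predicted Δ6MWD."""
    preds = np.asarray(predictions, dtype=float)
    if preds.size < 4:
        raise SchemaError("quartile stratification needs at least 4 predictions")
    t1, t2, t3 = np.percentile(preds, [25.0, 50.0, 75.0], method="linear")
    if not (t1 < t2 < t3):
        raise SchemaError(
            "tied quartile thresholds leave an empty stratum; review the tie policy "
            f"(thresholds {t1}, {t2}, {t3})"
        )
    assignment = np.array([_bin_index(v, (t1, t2, t3)) for v in preds], dtype=int)
    counts = {lab: int((assignment == i).sum()) for i, lab in enumerate(labels)}
    return QuartileStrata(
        thresholds=(float(t1), float(t2), float(t3)),
        labels=labels,
        assignment=assignment,
        counts=counts,
    )


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def stratum_summaries(
    intervals: Sequence[FollowUpInterval],
    strata: QuartileStrata,
) -> pd.DataFrame:
    """Per-stratum descriptives of outcome and baseline characteristics.

    Rows are characteristics, columns the four strata; continuous measures
    report mean (SD), the outcome additionally median/IQR, and categorical
    measures counts.
    """
    if len(intervals) != len(strata.assignment):
        raise SchemaError("intervals and stratum assignment must align")
    records = []
    for iv, k in zip(intervals, strata.assignment):
        b = iv.baseline_visit
        records.append(
            {
                "stratum": strata.labels[k],
                "delta6mwd": iv.delta6mwd,
                "lost_ambulation": iv.lost_ambulation,
                "age": b.age,
                "height": b.height,
                "weight": b.weight,
                "bmi": b.weight / (b.height / 100.0) ** 2,
                "baseline_6mwd": b.six_mwd,
                "steroid_duration": b.steroid_duration,
                "tft_10mwr_time": b.tft_10mwr_time if b.tft_10mwr_able else np.nan,
                "tft_rise_able": b.tft_rise_able,
                "tft_rise_time": b.tft_rise_time if b.tft_rise_able else np.nan,
                "tft_4sc_able": b.tft_4sc_able,
                "tft_4sc_time": b.tft_4sc_time if b.tft_4sc_able else np.nan,
                "genotype": b.genotype,
            }
        )
    frame = pd.DataFrame(records)

    out: dict[str, dict[str, float]] = {}
    for lab in strata.labels:
        sub = frame[frame["stratum"] == lab]
        col: dict[str, float] = {"n": len(sub)}
        d = sub["delta6mwd"].to_numpy()
        if len(sub):
            col["delta6mwd_mean"], col["delta6mwd_sd"] = _mean_sd(d)
            col["delta6mwd_median"] = float(np.median(d))
            col["delta6mwd_q1"], col["delta6mwd_q3"] = map(float, np.percentile(d, [25, 75]))
            for name in (
                "age",
                "height",
                "weight",
                "bmi",
                "baseline_6mwd",
                "steroid_duration",
            ):
                col[f"{name}_mean"], col[f"{name}_sd"] = _mean_sd(sub[name].to_numpy())
            for test in ("10mwr", "rise", "4sc"):
                times = sub[f"tft_{test}_time"].dropna().to_numpy()
                if times.size:
                    col[f"tft_{test}_time_mean"], col[f"tft_{test}_time_sd"] = _mean_sd(times)
            col["n_able_rise"] = int(sub["tft_rise_able"].sum())
            col["n_able_4sc"] = int(sub["tft_4sc_able"].sum())
            col["n_lost_ambulation"] = int(sub["lost_ambulation"].sum())
            for g in frame["genotype"].unique():
                col[f"genotype_{g}"] = int((sub["genotype"] == g).sum())
        out[lab] = col
    return pd.DataFrame(out)


def box_summary(
    intervals: Sequence[FollowUpInterval],
    strata: QuartileStrata,
    whisker: float = 1.5,
) -> dict:
    """Median/IQR/whisker summary of observed Δ6MWD per stratum (box plot data)."""
    out = {}
    deltas = np.array([iv.delta6mwd for iv in intervals])
    for i, lab in enumerate(strata.labels):
        d = deltas[strata.assignment == i]
        if d.size == 0:
            out[lab] = None
            continue
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        lo_fence, hi_fence = q1 - whisker * (q3 - q1), q3 + whisker * (q3 - q1)
        inside = d[(d >= lo_fence) & (d <= hi_fence)]
        out[lab] = {
            "n": int(d.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "outliers": [float(v) for v in d[(d < lo_fence) | (d > hi_fence)]],
        }
    return out
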