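"""Covariate encoding: from follow-up intervals to numeric design matrices.

Three canonical prognostic models are provided:

* ``MODEL1`` — the conventional factors: age, steroid use >= 1 year, baseline
  6MWD.
* ``MODEL2`` — the broad composite: Model 1 plus height, weight, BMI and the
  three timed function tests, each TFT entering as two parts (an ability
  indicator, and the time in seconds set to 0 for patients unable to
  complete).
* ``MODEL3`` — Model 2 plus dystrophin genotype class dummies (reference:
  deletion, the largest class).

A separate 30-second cap rule exists for the descriptive correlation analysis
only; it is never used when building model matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import GENOTYPE_CLASSES, TFT_TESTS, VisitRecord
from .errors import DataIntegrityError, SchemaError
from .intervals import FollowUpInterval

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "MODEL1",
    "MODEL2",
    "MODEL3",
    "encode_tft",
    "cap_tft_for_correlation",
    "transform_tft",
    "encode_model_matrix",
    "TFT_DISTANCES",
]

logger = logging.getLogger(__name__)

#: Distance covered by each timed test, used by the velocity transform
#: (10 m for the walk/run, 4 stairs for the climb, 1 for rise from supine).
TFT_DISTANCES = {"10mwr": 10.0, "4sc": 4.0, "rise": 1.0}

_SIMPLE_TERMS = {
    "intercept",
    "age",
    "steroid_ge1yr",
    "baseline_6mwd",
    "height",
    "weight",
    "bmi",
    "genotype",
}
_TFT_TERM_KINDS = {"tft_time", "tft_able", "tft_velocity", "tft_reciprocal", "tft_threshold"}


def _parse_term(term: str) -> tuple[str, tuple]:
    parts = term.split(":")
    kind = parts[0]
    if kind in _SIMPLE_TERMS:
        if len(parts) != 1:
            raise SchemaError(f"term {term!r} takes no arguments")
        return kind, ()
    if kind in _TFT_TERM_KINDS:
        if len(parts) < 2 or parts[1] not in TFT_TESTS:
            raise SchemaError(f"term {term!r} must name a test among {TFT_TESTS}")
        if kind == "tft_threshold":
            if len(parts) != 3:
                raise SchemaError(f"term {term!r} needs a cutoff, e.g. 'tft_threshold:rise:5'")
            return kind, (parts[1], float(parts[2]))
        if len(parts) != 2:
            raise SchemaError(f"term {term!r} takes exactly one test argument")
        return kind, (parts[1],)
    raise SchemaError(f"unknown model term {term!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A named, ordered covariate set."""

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.terms.count("intercept") != 1:
            raise SchemaError(f"model {self.name!r} must contain 'intercept' exactly once")
        if len(set(self.terms)) != len(self.terms):
            raise SchemaError(f"model {self.name!r} has duplicate terms")
        for term in self.terms:
            _parse_term(term)

    def with_terms(self, name: str, terms: Sequence[str]) -> "ModelSpec":
        return ModelSpec(name=name, terms=tuple(terms))

    def add(self, *extra: str, name: str | None = None) -> "ModelSpec":
        return ModelSpec(name or f"{self.name}+{'+'.join(extra)}", self.terms + tuple(extra))

    def drop(self, *gone: str, name: str | None = None) -> "ModelSpec":
        kept = tuple(t for t in self.terms if t not in gone)
        return ModelSpec(name or f"{self.name}-{'-'.join(gone)}", kept)


MODEL1 = ModelSpec("Model 1", ("intercept", "age", "steroid_ge1yr", "baseline_6mwd"))

# Column layout follows the reporting convention of natural-history
# prognostic analyses in this disease; the 10 m
# walk/run carries no ability indicator there (every patient completed it).
MODEL2 = ModelSpec(
    "Model 2",
    (
        "intercept",
        "age",
        "steroid_ge1yr",
        "baseline_6mwd",
        "height",
        "weight",
        "bmi",
        "tft_time:10mwr",
        "tft_able:rise",
        "tft_time:rise",
        "tft_able:4sc",
        "tft_time:4sc",
    ),
)

MODEL3 = MODEL2.add("genotype", name="Model 3")


@dataclass
class DesignMatrix:
    """Numeric design for a GEE fit: rows = intervals, clusters = patients."""

    row_keys: list[str]
    cluster_ids: np.ndarray  # object array of patient ids, aligned to rows
    column_names: list[str]
    values: np.ndarray  # (n_rows, n_cols)
    outcome: np.ndarray  # annualized Δ6MWD, m/year
    spec: Optional[ModelSpec] = None
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.row_keys)
        if not (self.values.shape[0] == n == len(self.cluster_ids) == len(self.outcome)):
            raise SchemaError("design rows, cluster ids and outcome must align")
        if self.values.shape[1] != len(self.column_names):
            raise SchemaError("column_names must match the value matrix width")
        if not np.isfinite(self.values).all() or not np.isfinite(self.outcome).all():
            raise SchemaError("design matrix must not contain absent values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return DesignMatrix(
            row_keys=[self.row_keys[i] for i in idx],
            cluster_ids=self.cluster_ids[idx],
            column_names=list(self.column_names),
            values=self.values[idx],
            outcome=self.outcome[idx],
            spec=self.spec,
            dropped_columns=list(self.dropped_columns),
        )


def encode_tft(time: Optional[float], able: bool) -> tuple[int, float]:
    """Two-part encoding of a timed test: (ability indicator, time-or-zero).

    Patients unable to complete contribute (0, 0); a completed test carries
    its time in seconds.
    """
    if able:
        if time is None or time != time:
            raise DataIntegrityError("able=True requires a completion time")
        return 1, float(time)
    return 0, 0.0


def cap_tft_for_correlation(time: Optional[float], able: bool, cap: float = 30.0) -> float:
    """Capped time used only by the descriptive correlation analysis.

    Patients who could not complete a test in under ``cap`` seconds are
    assigned the cap itself.
    """
    if able:
        if time is None or time != time:
            raise DataIntegrityError("able=True requires a completion time")
        if time < 0:
            raise ValueError("negative completion time")
        return min(float(time), cap)
    return float(cap)


def transform_tft(
    time: Optional[float],
    able: bool,
    kind: str,
    test: str = "10mwr",
    cutoff: float | None = None,
) -> float:
    """Alternative TFT encodings: velocity, reciprocal time, or a threshold.

    Unable always maps to 0, matching the continuity convention of the
    two-part encoding (slower-than-any-completion and unable coincide in the
    limit).
    """
    able01, time0 = encode_tft(time, able)
    if able01 == 0:
        return 0.0
    if kind == "velocity":
        if time0 == 0:
            raise ValueError("velocity undefined for zero completion time")
        return TFT_DISTANCES[test] / time0
    if kind == "reciprocal":
        if time0 == 0:
            raise ValueError("reciprocal undefined for zero completion time")
        return 1.0 / time0
    if kind == "threshold":
        if cutoff is None:
            raise ValueError("threshold transform needs a cutoff")
        return 1.0 if time0 <= cutoff else 0.0
    raise ValueError(f"unknown transform kind {kind!r}")


def _term_columns(term: str) -> list[str]:
    kind, args = _parse_term(term)
    if kind == "genotype":
        return [f"genotype_{g}" for g in GENOTYPE_CLASSES[1:]]
    if kind in _TFT_TERM_KINDS:
        test = args[0]
        if kind == "tft_threshold":
            return [f"tft_threshold_{test}_le{args[1]:g}"]
        return [f"{kind}_{test}"]
    return [kind]


def _term_values(base: VisitRecord, term: str, steroid_threshold: float) -> list[float]:
    kind, args = _parse_term(term)
    if kind == "intercept":
        return [1.0]
    if kind == "age":
        return [base.age]
    if kind == "steroid_ge1yr":
        return [1.0 if base.steroid_duration >= steroid_threshold else 0.0]
    if kind == "baseline_6mwd":
        return [base.six_mwd]
    if kind == "height":
        return [base.height]
    if kind == "weight":
        return [base.weight]
    if kind == "bmi":
        return [base.weight / (base.height / 100.0) ** 2]
    if kind == "genotype":
        return [1.0 if base.genotype == g else 0.0 for g in GENOTYPE_CLASSES[1:]]
    test = args[0]
    time, able = base.tft(test)
    if kind == "tft_time":
        return [encode_tft(time, able)[1]]
    if kind == "tft_able":
        return [float(encode_tft(time, able)[0])]
    if kind == "tft_velocity":
        return [transform_tft(time, able, "velocity", test)]
    if kind == "tft_reciprocal":
        return [transform_tft(time, able, "reciprocal", test)]
    if kind == "tft_threshold":
        return [transform_tft(time, able, "threshold", test, cutoff=args[1])]
    raise SchemaError(f"unknown model term {term!r}")  # pragma: no cover


def encode_model_matrix(
    intervals: Sequence[FollowUpInterval],
    spec: ModelSpec,
    steroid_threshold: float = 1.0,
    drop_constant_able: bool = True,
) -> DesignMatrix:
    """Build the numeric design matrix for a model over follow-up intervals.

    Ability-indicator columns that are constant in the data (e.g. every
    patient completed the 10 m walk/run) carry no information and are dropped
    with a logged notice; the drop is recorded on the returned matrix.
    """
    if not intervals:
        raise SchemaError("cannot encode an empty interval list")
    columns: list[str] = []
    for term in spec.terms:
        columns.extend(_term_columns(term))

    rows = np.empty((len(intervals), len(columns)), dtype=float)
    cluster = np.empty(len(intervals), dtype=object)
    outcome = np.empty(len(intervals), dtype=float)
    keys: list[str] = []
    for i, iv in enumerate(intervals):
        base = iv.baseline_visit
        vals: list[float] = []
        for term in spec.terms:
            try:
                vals.extend(_term_values(base, term, steroid_threshold))
            except DataIntegrityError as err:
                raise DataIntegrityError(
                    f"interval {iv.patient_id}@{base.date_offset}d, term {term!r}: {err}"
                ) from err
        rows[i] = vals
        cluster[i] = iv.patient_id
        outcome[i] = iv.delta6mwd
        keys.append(f"{iv.patient_id}:{base.date_offset}->{iv.followup_visit.date_offset}")

    dropped: list[str] = []
    if drop_constant_able:
        keep = np.ones(len(columns), dtype=bool)
        for j, name in enumerate(columns):
            droppable = name.startswith("tft_able_") or name.startswith("genotype_")
            if droppable and np.ptp(rows[:, j]) == 0.0:
                keep[j] = False
                dropped.append(name)
                logger.warning("dropping constant indicator column %s", name)
        rows = rows[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]

    return DesignMatrix(
        row_keys=keys,
        cluster_ids=cluster,
        column_names=columns,
        values=rows,
        outcome=outcome,
        spec=spec,
        dropped_columns=dropped,
    )
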