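"""Construction of approximate 1-year follow-up intervals.

The outcome of the analysis is the annualized change in 6MWD between a
baseline visit and a follow-up visit 8-16 months later.  Every ordered
same-patient visit pair satisfying the inclusion rules is emitted; a visit may
serve as the baseline of several intervals and as the follow-up of others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import VisitRecord
from .errors import DataIntegrityError

__all__ = [
    "WindowPolicy",
    "FollowUpInterval",
    "annualized_change",
    "build_intervals",
    "intervals_to_frame",
]

DAYS_PER_YEAR = 365.25

#: Baseline fields that must be present for the broad prognostic model
#: (ability flags are always present; a TFT time may be absent only when the
#: corresponding flag is False, which is a valid, non-missing measurement).
DEFAULT_REQUIRED_FIELDS = (
    "age",
    "height",
    "weight",
    "six_mwd",
    "steroid_duration",
    "tft_rise_able",
    "tft_10mwr_able",
    "tft_4sc_able",
)


@dataclass(frozen=True)
class WindowPolicy:
    """Inclusion window for follow-up visits.

    Elapsed months are computed as ``elapsed_days / days_per_month`` with a
    fixed-length month (the mean Gregorian month by default); the window is
    inclusive at both ends.
    """

    min_months: float = 8.0
    max_months: float = 16.0
    days_per_month: float = 30.4375
    required_baseline_fields: tuple[str, ...] = DEFAULT_REQUIRED_FIELDS

    def __post_init__(self) -> None:
        if not (0 < self.min_months < self.max_months):
            raise ValueError("window requires 0 < min_months < max_months")

    def admits(self, elapsed_days: float) -> bool:
        months = elapsed_days / self.days_per_month
        return self.min_months <= months <= self.max_months


@dataclass(frozen=True)
class FollowUpInterval:
    """An ordered visit pair with its annualized 6MWD outcome."""

    patient_id: str
    baseline_visit: VisitRecord
    followup_visit: VisitRecord
    elapsed_days: float
    elapsed_years: float
    delta6mwd: float  # m/year
    lost_ambulation: bool  # follow-up 6MWD = 0


def annualized_change(baseline_6mwd: float, followup_6mwd: float, elapsed_days: float) -> float:
    """Annualized change in walk distance, m/year.

    ``(follow-up - baseline) * 365.25 / elapsed_days``; the baseline must be a
    completed (positive) walk and the elapsed time strictly positive.
    """
    if elapsed_days <= 0:
        raise ValueError(f"elapsed_days must be > 0, got {elapsed_days}")
    if baseline_6mwd <= 0:
        raise ValueError("baseline 6MWD must be > 0 for an annualized change")
    if followup_6mwd < 0:
        raise ValueError("follow-up 6MWD cannot be negative")
    return (followup_6mwd - baseline_6mwd) * DAYS_PER_YEAR / elapsed_days


def _baseline_complete(visit: VisitRecord, fields: tuple[str, ...]) -> bool:
    for name in fields:
        value = getattr(visit, name)
        if value is None or value != value:  # NaN check without numpy import
            return False
    # able/time consistency: a completed test must carry its time
    for test in ("rise", "10mwr", "4sc"):
        time, able = visit.tft(test)
        if able and time is None:
            return False
    return True


def build_intervals(
    visits: list[VisitRecord],
    policy: WindowPolicy | None = None,
) -> list[FollowUpInterval]:
    """Enumerate every qualifying baseline -> follow-up visit pair.

    A pair qualifies when (1) the baseline 6MWD is positive, (2) the follow-up
    lies inside the policy's 8-16 month window, and (3) every required
    baseline field is present.  All qualifying pairs are returned, sorted by
    (patient, baseline date, follow-up date).
    """
    policy = policy or WindowPolicy()
    by_patient: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_patient.setdefault(v.patient_id, []).append(v)

    intervals: list[FollowUpInterval] = []
    for pid in sorted(by_patient):
        pvisits = sorted(by_patient[pid], key=lambda v: v.date_offset)
        offsets = [v.date_offset for v in pvisits]
        if len(set(offsets)) != len(offsets):
            raise DataIntegrityError(f"duplicate visit date_offset for patient {pid}")
        for i, base in enumerate(pvisits):
            if base.six_mwd <= 0:
                continue
            if not _baseline_complete(base, policy.required_baseline_fields):
                continue
            for fup in pvisits[i + 1 :]:
                elapsed = float(fup.date_offset - base.date_offset)
                if not policy.admits(elapsed):
                    continue
                years = elapsed / DAYS_PER_YEAR
                delta = annualized_change(base.six_mwd, fup.six_mwd, elapsed)
                intervals.append(
                    FollowUpInterval(
                        patient_id=pid,
                        baseline_visit=base,
                        followup_visit=fup,
                        elapsed_days=elapsed,
                        elapsed_years=years,
                        delta6mwd=delta,
                        lost_ambulation=fup.six_mwd == 0.0,
                    )
                )
    return intervals


def intervals_to_frame(intervals: list[FollowUpInterval]) -> pd.DataFrame:
    """Flatten intervals to a table, baseline covariates prefixed ``bl_``."""
    rows = []
    for iv in intervals:
        row = {
            "patient_id": iv.patient_id,
            "elapsed_days": iv.elapsed_days,
            "elapsed_years": iv.elapsed_years,
            "delta6mwd": iv.delta6mwd,
            "lost_ambulation": iv.lost_ambulation,
            "followup_6mwd": iv.followup_visit.six_mwd,
        }
        for name, value in vars(iv.baseline_visit).items():
            if name == "patient_id":
                continue
            row[f"bl_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
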