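"""Toxicity-endpoint scoring of ANC trajectories and cohort summaries.

Severity follows the CTCAE neutropenia thresholds: grade 3 below 1E9
cells/L, grade 4 below 5E8 cells/L, with recovery defined as a return above
the grade-2 threshold (1.5E9 cells/L by convention, configurable).  The
hourly simulation is reduced to one value per calendar day — the daily
minimum, a conservative choice — and every endpoint is evaluated on that
daily series within the first 28-day cycle:

* any neutropenic day below a threshold (single event incidence),
* at least 7 consecutive neutropenic days (the dose-limiting pattern),
* recovery above the grade-2 threshold after first onset, and its delay,
* the day of the ANC nadir (earliest day on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pkpd import ExposureMetrics

__all__ = [
    "GRADE3_THRESHOLD",
    "GRADE4_THRESHOLD",
    "GRADE2_THRESHOLD",
    "ToxicityEvent",
    "CohortToxicitySummary",
    "daily_anc",
    "grade_events",
    "recovery",
    "time_to_nadir",
    "summarize_cohort",
    "scenario_grid",
]

GRADE3_THRESHOLD = 1e9   # cells/L
GRADE4_THRESHOLD = 5e8   # cells/L
GRADE2_THRESHOLD = 1.5e9  # cells/L; "above grade 2" recovery level

CYCLE_DAYS = 28


@dataclass(frozen=True)
class ToxicityEvent:
    """One maximal run of consecutive neutropenic days below a threshold."""

    grade: int
    start_day: int  # 1-based, inclusive
    end_day: int    # 1-based, inclusive
    threshold: float

    @property
    def duration_days(self) -> int:
        return self.end_day - self.start_day + 1


def daily_anc(series, n_days: int = CYCLE_DAYS) -> np.ndarray:
    """Reduce an hourly ANC series to one value per calendar day.

    Day ``d`` (1-based) covers hours [24(d-1), 24d), with the final day
    closed on the right; the daily value is the minimum over that window, so
    an endpoint is triggered by any excursion below threshold during the day.
    """
    t, a = series.times, series.anc
    if t.size == 0:
        raise ValueError("empty ANC series")
    if t.max() < (n_days - 1) * 24.0:
        raise ValueError(f"series does not cover {n_days} days")
    out = np.empty(n_days)
    for d in range(n_days):
        hi = 24.0 * (d + 1)
        mask = (t >= 24.0 * d) & ((t <= hi) if d == n_days - 1 else (t < hi))
        out[d] = a[mask].min()
    return out


def grade_events(series, threshold: float, n_days: int = CYCLE_DAYS) -> list[ToxicityEvent]:
    """Maximal below-threshold runs of the daily ANC within the first cycle."""
    daily = series if isinstance(series, np.ndarray) else daily_anc(series, n_days)
    below = daily < threshold
    grade = 4 if threshold <= GRADE4_THRESHOLD else 3
    events: list[ToxicityEvent] = []
    start = None
    for d, flag in enumerate(below, start=1):
        if flag and start is None:
            start = d
        elif not flag and start is not None:
            events.append(ToxicityEvent(grade, start, d - 1, threshold))
            start = None
    if start is not None:
        events.append(ToxicityEvent(grade, start, len(daily), threshold))
    return events


def recovery(
    series,
    events: list[ToxicityEvent],
    grade2_threshold: float = GRADE2_THRESHOLD,
    n_days: int = CYCLE_DAYS,
) -> tuple[bool, float | None]:
    """Recovery above the grade-2 threshold after first toxicity onset.

    Returns ``(recovered, time_to_recovery_days)``; the delay runs from the
    first onset day to the first later day whose ANC exceeds the grade-2
    threshold, and is None when no recovery occurs within the cycle.
    """
    if not events:
        raise ValueError("recovery is only defined after a toxicity event")
    daily = series if isinstance(series, np.ndarray) else daily_anc(series, n_days)
    onset = min(e.start_day for e in events)
    after = np.nonzero(daily[onset:] > grade2_threshold)[0]  # daily[onset] is day onset+1
    if after.size == 0:
        return False, None
    return True, float(after[0] + 1)


def time_to_nadir(series, n_days: int = CYCLE_DAYS) -> int:
    """Day (1-28) of the minimum daily ANC; ties broken to the earliest day."""
    daily = series if isinstance(series, np.ndarray) else daily_anc(series, n_days)
    return int(np.argmin(daily)) + 1


@dataclass
class CohortToxicitySummary:
    """Per-scenario cohort toxicity summary (one published-table row).

    Percentages are over the whole cohort; mean recovery times average over
    recovered patients only (NaN when nobody recovered).
    """

    n_patients: int
    gr3_single_pct: float
    gr4_single_pct: float
    gr3_7day_pct: float
    gr4_7day_pct: float
    recovered_gr3_pct: float
    recovered_gr4_pct: float
    mean_time_to_recovery_gr3_days: float
    mean_time_to_recovery_gr4_days: float
    nadir_days: np.ndarray = field(repr=False)
    auc_cycle1: float = np.nan
    cmax: float = np.nan
    dose_mg: float | None = None
    schedule: str | None = None

    @property
    def modal_nadir_day(self) -> int:
        vals, counts = np.unique(self.nadir_days, return_counts=True)
        return int(vals[np.argmax(counts)])

    def to_row(self) -> dict:
        return {
            "dose_mg": self.dose_mg,
            "schedule": self.schedule,
            "n_patients": self.n_patients,
            "gr3_single_pct": self.gr3_single_pct,
            "gr4_single_pct": self.gr4_single_pct,
            "gr3_7day_pct": self.gr3_7day_pct,
            "gr4_7day_pct": self.gr4_7day_pct,
            "recovered_gr3_pct": self.recovered_gr3_pct,
            "recovered_gr4_pct": self.recovered_gr4_pct,
            "mean_time_to_recovery_gr3_days": self.mean_time_to_recovery_gr3_days,
            "mean_time_to_recovery_gr4_days": self.mean_time_to_recovery_gr4_days,
            "modal_nadir_day": self.modal_nadir_day,
            "auc_cycle1_ng_h_per_ml": self.auc_cycle1,
            "cmax_ng_per_ml": self.cmax,
        }


def _grade_stats(daily_mat: np.ndarray, threshold: float, grade2: float):
    n = daily_mat.shape[0]
    single = 0
    seven = 0
    recovered = 0
    rec_times = []
    for row in daily_mat:
        events = grade_events(row, threshold)
        if not events:
            continue
        single += 1
        if max(e.duration_days for e in events) >= 7:
            seven += 1
        rec, tt = recovery(row, events, grade2)
        if rec:
            recovered += 1
            rec_times.append(tt)
    pct = 100.0 / n
    return (
        single * pct,
        seven * pct,
        recovered * pct,
        float(np.mean(rec_times)) if rec_times else float("nan"),
    )


def summarize_cohort(
    series_list,
    grade3: float = GRADE3_THRESHOLD,
    grade4: float = GRADE4_THRESHOLD,
    grade2: float = GRADE2_THRESHOLD,
    exposure: ExposureMetrics | None = None,
    dose_mg: float | None = None,
    schedule: str | None = None,
) -> CohortToxicitySummary:
    """Aggregate per-patient endpoints into one scenario summary."""
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one ANC series")
    daily_mat = np.array([daily_anc(s) for s in series_list])
    g3 = _grade_stats(daily_mat, grade3, grade2)
    g4 = _grade_stats(daily_mat, grade4, grade2)
    nadirs = np.array([time_to_nadir(row) for row in daily_mat])
    return CohortToxicitySummary(
        n_patients=len(series_list),
        gr3_single_pct=g3[0],
        gr4_single_pct=g4[0],
        gr3_7day_pct=g3[1],
        gr4_7day_pct=g4[1],
        recovered_gr3_pct=g3[2],
        recovered_gr4_pct=g4[2],
        mean_time_to_recovery_gr3_days=g3[3],
        mean_time_to_recovery_gr4_days=g4[3],
        nadir_days=nadirs,
        auc_cycle1=exposure.auc_cycle1 if exposure else np.nan,
        cmax=exposure.cmax if exposure else np.nan,
        dose_mg=dose_mg,
        schedule=schedule,
    )


def scenario_grid(
    cohort,
    doses,
    schedules,
    pk,
    pd_params,
    *,
    grade3: float = GRADE3_THRESHOLD,
    grade4: float = GRADE4_THRESHOLD,
    grade2: float = GRADE2_THRESHOLD,
    rtol: float = 1e-6,
    atol: float = 1e3,
    **sim_kwargs,
) -> pd.DataFrame:
    """Virtual dose/schedule trial: one summary row per (dose, schedule).

    The same cohort is reused across every scenario so that differences
    between rows reflect the regimen, not cohort sampling.  ``schedules`` are
    'days_on/period' strings (e.g. '5/7'); simulation failures propagate with
    the offending scenario label attached.
    """
    from .pkpd import Regimen, dosing_times, exposure_metrics, pk_concentration
    from .simulate import simulate_cohort

    doses = list(doses)
    schedules = list(schedules)
    if not doses or not schedules:
        raise ValueError("need at least one dose and one schedule")

    rows = []
    summaries = []
    for sched in schedules:
        for dose in doses:
            reg = Regimen.parse(f"{dose}mg {sched}")
            try:
                results = simulate_cohort(
                    cohort, pk, pd_params, reg, rtol=rtol, atol=atol, **sim_kwargs
                )
            except Exception as exc:
                raise RuntimeError(f"scenario {dose}mg {sched} failed: {exc}") from exc
            grid = results[0].series.times
            exp = exposure_metrics(grid, results[0].conc)
            summ = summarize_cohort(
                [r.series for r in results],
                grade3=grade3, grade4=grade4, grade2=grade2,
                exposure=exp, dose_mg=float(dose), schedule=sched,
            )
            summaries.append(summ)
            rows.append(summ.to_row())
    df = pd.DataFrame(rows)
    df.attrs["summaries"] = summaries
    return df
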