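"""Time-to-event derivation, Kaplan-Meier cumulative incidence, log-rank and
person-year incidence rates.

The event is the first high-dose treatment episode; its date is the episode
midpoint, so the event time is days from cohort entry to that midpoint.
Follow-up is capped at 24 months and censored at the earliest of death from
any cause, loss to follow-up (end of enrolment) and the administrative cap
-- death is treated as censoring, not a competing risk, so the cumulative
incidence is F(t) = 1 - S(t) with S the Kaplan-Meier estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import FollowupConfig
from .errors import DataError, DataIntegrityError


def derive_time_to_event(
    entries: pd.DataFrame,
    summaries: pd.DataFrame,
    deaths: pd.DataFrame,
    enrolment: pd.DataFrame,
    config: FollowupConfig | None = None,
) -> pd.DataFrame:
    """Per-patient follow-up time and high-dose event indicator.

    ``summaries`` is the per-patient exposure summary for the index drug
    (``first_high_dose_midpoint`` is the event date when present).  The event
    counts when its date falls on or before every censoring time; otherwise
    the patient is censored at the earliest of death, enrolment end and
    ``max_followup_days``, with the censoring reason resolved in
    ``config.censoring_priority`` order on ties.
    """
    config = config or FollowupConfig()
    cap = config.max_followup_days

    out = entries[["patient_id", "index_drug", "entry_date"]].copy()
    out = out.rename(columns={"index_drug": "cohort"})
    out["entry_date"] = pd.to_datetime(out["entry_date"])

    s = summaries.rename(columns={"drug": "cohort"})
    out = out.merge(
        s[["patient_id", "cohort", "first_high_dose_midpoint"]],
        on=["patient_id", "cohort"],
        how="left",
    )

    dd = deaths.copy()
    dd["death_date"] = pd.to_datetime(dd["death_date"])
    death_map = dd.groupby("patient_id")["death_date"].min()
    out["death_date"] = out["patient_id"].map(death_map)
    if (out["death_date"] < out["entry_date"]).any():
        pid = out.loc[out["death_date"] < out["entry_date"], "patient_id"].iloc[0]
        raise DataIntegrityError(f"death before cohort entry for patient {pid}")

    enr = enrolment.copy()
    enr["end_date"] = pd.to_datetime(enr["end_date"])
    enr_end = enr.groupby("patient_id")["end_date"].max()
    out["enrolment_end"] = out["patient_id"].map(enr_end)

    death_days = (out["death_date"] - out["entry_date"]).dt.days.astype("Float64")
    loss_days = (out["enrolment_end"] - out["entry_date"]).dt.days.astype("Float64")
    event_days = (
        pd.to_datetime(out["first_high_dose_midpoint"]) - out["entry_date"]
    ).dt.days.astype("Float64")

    d = death_days.to_numpy(dtype=float, na_value=np.inf)
    l = loss_days.to_numpy(dtype=float, na_value=np.inf)
    e = event_days.to_numpy(dtype=float, na_value=np.inf)

    censor_candidates = {"death": d, "loss": l, "admin": np.full(len(out), float(cap))}
    censor_time = np.minimum(np.minimum(d, l), float(cap))
    event = e <= censor_time
    time = np.where(event, e, censor_time)

    reason = np.full(len(out), "none", dtype=object)
    for name in reversed(list(config.censoring_priority)):
        hit = ~event & (censor_candidates[name] == censor_time)
        reason[hit] = name

    time = np.maximum(time, 0.5)  # zero-day events clamp to half a day
    return pd.DataFrame(
        {
            "patient_id": out["patient_id"],
            "cohort": out["cohort"],
            "time_days": time,
            "event": event.astype(int),
            "censor_reason": reason,
        }
    )


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate, right-continuous in t."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    @property
    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t) -> np.ndarray:
        """S(t) by right-continuous step interpolation; S(t)=1 before the
        first event."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if np.ndim(t) else float(out[0])

    def incidence_at(self, t):
        s = self.survival_at(t)
        return 1.0 - s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "cumulative_incidence": self.cumulative_incidence,
            }
        )


def kaplan_meier(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimate of S(t) from time/event records.

    Ties are handled by simultaneous events: all events at a time t share the
    same at-risk set; censorings at t leave the risk set after the events.
    """
    if len(records) == 0:
        raise DataError("kaplan_meier requires at least one record")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], records["event"])
    table = kmf.event_table.loc[kmf.event_table["observed"] > 0]
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    return KMCurve(
        event_times=times,
        n_at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def log_rank(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi_square, p_value).

    Symmetric in group order; 1 df.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise DataError("log_rank requires two non-empty groups")
    from lifelines.statistics import logrank_test

    res = logrank_test(
        records_a["time_days"],
        records_b["time_days"],
        event_observed_A=records_a["event"],
        event_observed_B=records_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def format_p(p: float, floor: float = 0.0001) -> str:
    """Report style: very small p-values are floored as 'p < 0.0001'."""
    return f"p < {floor:g}" if p < floor else f"p = {p:.4f}"


@dataclass
class IncidenceRate:
    events: int
    person_years: float
    rate_per_1000py: float
    ci95: tuple[float, float]
    ci_method: str

    def to_dict(self) -> dict:
        return {
            "events": int(self.events),
            "person_years": float(self.person_years),
            "rate_per_1000py": float(self.rate_per_1000py),
            "ci95_low": float(self.ci95[0]),
            "ci95_high": float(self.ci95[1]),
            "ci_method": self.ci_method,
        }


def incidence_rate_from_counts(
    events: int, person_years: float, ci_method: str = "wald_natural"
) -> IncidenceRate:
    """Incidence rate per 1000 person-years with a 95% CI.

    ``wald_natural``: rate +/- 1.96 * rate/sqrt(D) on the natural scale.
    ``poisson_exact``: chi-square (Garwood) bounds on the event count.
    With zero events the Wald interval is undefined and the computation
    falls back to the exact bounds with a warning.
    """
    if person_years <= 0:
        raise DataError("incidence rate requires person_years > 0")
    if ci_method not in ("wald_natural", "poisson_exact"):
        raise DataError(f"unknown ci_method {ci_method!r}")
    rate = 1000.0 * events / person_years
    if events == 0 and ci_method == "wald_natural":
        warnings.warn(
            "zero events: falling back to poisson_exact CI", stacklevel=2
        )
        ci_method = "poisson_exact"
    if ci_method == "wald_natural":
        half = 1.96 * rate / np.sqrt(events)
        ci = (rate - half, rate + half)
    else:
        lo = 0.5 * stats.chi2.ppf(0.025, 2 * events) if events > 0 else 0.0
        hi = 0.5 * stats.chi2.ppf(0.975, 2 * (events + 1))
        ci = (1000.0 * lo / person_years, 1000.0 * hi / person_years)
    return IncidenceRate(int(events), float(person_years), rate, ci, ci_method)


def incidence_rate(
    records: pd.DataFrame,
    ci_method: str = "wald_natural",
    days_per_year: float = 365.25,
) -> IncidenceRate:
    """Incidence rate from time-to-event records (person-time = sum of
    individual follow-up divided by 365.25)."""
    person_years = float(records["time_days"].sum()) / days_per_year
    return incidence_rate_from_counts(
        int(records["event"].sum()), person_years, ci_method
    )
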