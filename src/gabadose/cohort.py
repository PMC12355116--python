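"""New-user cohort selection with an auditable attrition trail.

A new user of the index drug is a patient whose first in-window dispensing
(the cohort entry date) is followed by at least ``min_dispensings``
dispensings of that drug within the qualification year, preceded by a
drug-free washout year, who is an adult with known age and sex and has
continuous health-plan enrolment over the washout year.  Exclusion rules are
applied sequentially and each rejection is recorded under the first rule
that fires, so the attrition report conserves the screened total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DRUGS, EligibilityConfig
from .errors import DataIntegrityError

#: rule order: mirrors the study-population exclusion sequence (prevalent,
#: occasional, under-age, unknown demographics, non-continuous enrolment)
RULES = (
    "no_index_dispensing_in_window",
    "prevalent_user",
    "occasional_use",
    "under_min_age",
    "missing_demographics",
    "non_continuous_enrolment",
)


@dataclass
class AttritionReport:
    """Ordered per-rule exclusion counts; conservation holds exactly:
    ``n_screened - sum(n_excluded) == n_included``."""

    rules: list[tuple[str, int]]
    n_screened: int
    n_included: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("screened", self.n_screened)]
        rows += [(f"excluded_{r}", n) for r, n in self.rules]
        rows.append(("included", self.n_included))
        return pd.DataFrame(rows, columns=["step", "n"])


def _check_integrity(dispensings, patients, enrolment):
    orphan = ~dispensings["patient_id"].isin(patients["patient_id"])
    if orphan.any():
        pid = dispensings.loc[orphan, "patient_id"].iloc[0]
        raise DataIntegrityError(f"dispensing for unknown patient {pid}")
    enr = enrolment.sort_values(["patient_id", "start_date"])
    same = enr["patient_id"] == enr["patient_id"].shift()
    overlap = same & (enr["start_date"] <= enr["end_date"].shift())
    if overlap.any():
        pid = enr.loc[overlap, "patient_id"].iloc[0]
        raise DataIntegrityError(f"overlapping enrolment intervals for patient {pid}")


def _washout_covered(enrolment: pd.DataFrame, entries: pd.DataFrame, washout_days: int,
                     allowance: int) -> pd.Series:
    """True per entry when [entry - washout_days, entry] is covered by the
    union of the patient's enrolment intervals with at most ``allowance``
    uncovered days."""
    enr = enrolment.sort_values(["patient_id", "start_date"])
    merged = entries[["patient_id", "entry_date"]].merge(enr, on="patient_id", how="left")
    lo = merged["entry_date"] - pd.to_timedelta(washout_days, unit="D")
    hi = merged["entry_date"]
    start = merged["start_date"].where(merged["start_date"] > lo, lo)
    end = merged["end_date"].where(merged["end_date"] < hi, hi)
    covered = (end - start).dt.days + 1
    merged["covered"] = covered.clip(lower=0).where(merged["start_date"].notna(), 0)
    # intervals are non-overlapping (validated), so covered days add up
    total = merged.groupby("patient_id")["covered"].sum()
    need = washout_days + 1 - allowance
    ok = entries["patient_id"].map(total).fillna(0) >= need
    return ok.to_numpy()


def select_new_users(
    dispensings: pd.DataFrame,
    patients: pd.DataFrame,
    enrolment: pd.DataFrame,
    deaths: pd.DataFrame,
    config: EligibilityConfig | None = None,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply the inclusion/exclusion rules for one index drug.

    Returns the cohort entries (one row per included patient: entry date,
    age, sex, deprivation) and the ordered attrition report.  Every patient
    with at least one dispensing of the index drug is screened and lands in
    exactly one bucket (included or one exclusion rule).
    """
    config = config or EligibilityConfig()
    _check_integrity(dispensings, patients, enrolment)
    drug = config.index_drug

    disp = dispensings.loc[dispensings["drug"] == drug].copy()
    disp["date"] = pd.to_datetime(disp["date"])
    start = pd.Timestamp(config.inclusion_start)
    end = pd.Timestamp(config.inclusion_end)

    n_screened = disp["patient_id"].nunique()
    counts: dict[str, int] = {r: 0 for r in RULES}

    # entry date: first index-drug dispensing inside the inclusion window
    in_window = disp.loc[(disp["date"] >= start) & (disp["date"] <= end)]
    entry = in_window.groupby("patient_id")["date"].min().rename("entry_date")
    counts["no_index_dispensing_in_window"] = n_screened - len(entry)

    cand = entry.reset_index()
    first = disp.groupby("patient_id")["date"].min()
    merged = disp.merge(cand, on="patient_id")

    # prevalent: any index-drug dispensing in the washout before entry
    washout = pd.to_timedelta(config.washout_days, unit="D")
    if config.washout_drug_scope == "both_gabapentinoids":
        scope = dispensings.copy()
        scope["date"] = pd.to_datetime(scope["date"])
        merged = scope.merge(cand, on="patient_id")
    prev_mask = (merged["date"] < merged["entry_date"]) & (
        merged["date"] >= merged["entry_date"] - washout
    )
    prevalent_ids = set(merged.loc[prev_mask, "patient_id"])
    counts["prevalent_user"] = len(prevalent_ids)
    cand = cand.loc[~cand["patient_id"].isin(prevalent_ids)]

    # occasional: fewer than min_dispensings within the qualification window
    merged = disp.merge(cand, on="patient_id")
    qual = pd.to_timedelta(config.qualification_window_days, unit="D")
    q_mask = (merged["date"] >= merged["entry_date"]) & (
        merged["date"] <= merged["entry_date"] + qual
    )
    n_qual = merged.loc[q_mask].groupby("patient_id").size()
    qualified = n_qual[n_qual >= config.min_dispensings].index
    counts["occasional_use"] = len(cand) - len(qualified)
    cand = cand.loc[cand["patient_id"].isin(qualified)]

    # demographics
    pat = patients.set_index("patient_id")
    cand = cand.merge(
        pat[["birth_year", "sex", "deprivation_index"]],
        left_on="patient_id",
        right_index=True,
        how="left",
    )
    cand["age_at_entry"] = cand["entry_date"].dt.year - cand["birth_year"].astype(
        "Float64"
    )
    known = cand["birth_year"].notna() & cand["sex"].notna()
    minor = known & (cand["age_at_entry"] < config.min_age_years)
    counts["under_min_age"] = int(minor.sum())
    cand = cand.loc[~minor]
    known = cand["birth_year"].notna() & cand["sex"].notna()
    counts["missing_demographics"] = int((~known).sum())
    cand = cand.loc[known]

    # continuous enrolment over the washout year
    enr = enrolment.copy()
    enr["start_date"] = pd.to_datetime(enr["start_date"])
    enr["end_date"] = pd.to_datetime(enr["end_date"])
    ok = _washout_covered(
        enr, cand, config.washout_days, config.enrolment_gap_allowance_days
    )
    counts["non_continuous_enrolment"] = int((~ok).sum())
    cand = cand.loc[ok]

    entries = cand.reset_index(drop=True).copy()
    entries["index_drug"] = drug
    entries["age_at_entry"] = entries["age_at_entry"].astype(float)
    entries = entries[
        [
            "patient_id",
            "index_drug",
            "entry_date",
            "age_at_entry",
            "sex",
            "deprivation_index",
        ]
    ]
    report = AttritionReport(
        rules=[(r, counts[r]) for r in RULES],
        n_screened=n_screened,
        n_included=len(entries),
    )
    assert report.n_screened - sum(n for _, n in report.rules) == report.n_included
    return entries, report


def baseline_covariates(
    entries: pd.DataFrame,
    patients: pd.DataFrame,
    dispensings: pd.DataFrame,
    lookback_days: int = 365,
) -> pd.DataFrame:
    """Attach baseline covariates to cohort entries.

    Prior-exposure flags come from dispensings strictly before the entry
    date and at most ``lookback_days`` before it; comorbidity flags are
    copied from the patients table; the initial prescriber specialty is the
    specialty recorded on the entry-date dispensing (absent if unrecorded).
    """
    out = entries.copy()
    disp = dispensings.copy()
    disp["date"] = pd.to_datetime(disp["date"])

    # prior exposure to the other gabapentinoid
    other = {d: [o for o in DRUGS if o != d][0] for d in DRUGS}
    out["prior_other_gabapentinoid"] = 0
    merged = disp.merge(
        out[["patient_id", "entry_date", "index_drug"]], on="patient_id"
    )
    lb = pd.to_timedelta(lookback_days, unit="D")
    window = (merged["date"] < merged["entry_date"]) & (
        merged["date"] >= merged["entry_date"] - lb
    )
    is_other = merged["drug"] == merged["index_drug"].map(other)
    prior_ids = set(merged.loc[window & is_other, "patient_id"])
    out.loc[out["patient_id"].isin(prior_ids), "prior_other_gabapentinoid"] = 1

    # comorbidity / prior drug-class flags from the patients table
    core = {"patient_id", "birth_year", "sex", "deprivation_index"}
    flags = [c for c in patients.columns if c not in core]
    out = out.merge(patients[["patient_id"] + flags], on="patient_id", how="left")

    # initial prescriber: specialty on the entry-date index-drug dispensing
    entry_disp = merged.loc[
        (merged["date"] == merged["entry_date"])
        & (merged["drug"] == merged["index_drug"])
    ]
    spec = entry_disp.groupby("patient_id")["prescriber_specialty"].first()
    out["initial_prescriber_specialty"] = out["patient_id"].map(spec)

    out["man"] = (out["sex"] == "man").astype(int)
    return out
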