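"""End-to-end orchestration: cohorts, episodes, survival, Cox, trends.

``run_pipeline`` executes the stages per index drug and per sensitivity gap
threshold, writes every stage output under the output directory and records
a manifest (config hash, row counts per stage) so that a rerun with the same
inputs and config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import baseline_covariates, select_new_users
from .config import EpisodeConfig, PipelineConfig
from .cox import fit_cox, ph_diagnostics, report_factors
from .episodes import build_episodes_table, exposure_summary
from .errors import GabadoseError
from .io import read_tables
from .survival import derive_time_to_event, format_p, incidence_rate, kaplan_meier, log_rank
from .trends import monthly_initiations, stl_trend

log = logging.getLogger("gabadose")


def percentage(count: float, cohort_n: int, n_missing: int = 0) -> float:
    """Table-style percentage: the denominator excludes patients with a
    missing value for this field (age/sex have none, so they use the full
    cohort)."""
    denom = cohort_n - n_missing
    return round(100.0 * count / denom, 1)


def _median_iqr(x) -> dict:
    x = pd.Series(x).dropna()
    if len(x) == 0:
        return {"median": None, "q1": None, "q3": None}
    return {
        "median": float(x.median()),
        "q1": float(x.quantile(0.25)),
        "q3": float(x.quantile(0.75)),
    }


def describe_cohort(entries: pd.DataFrame) -> dict:
    """Baseline-table style descriptive report for one cohort.

    Continuous fields get median [IQR]; categorical fields get counts and
    percentages.  Percentage denominators exclude missing values for fields
    that can be missing (prescriber specialty, deprivation, comorbidity
    flags) and use the full cohort for age and sex.
    """
    n = len(entries)
    out: dict = {"n": n}
    out["age"] = _median_iqr(entries["age_at_entry"])
    sex_counts = entries["sex"].value_counts()
    out["sex"] = {
        s: {"n": int(c), "pct": percentage(int(c), n)} for s, c in sex_counts.items()
    }
    dep = entries["deprivation_index"]
    out["deprivation_index"] = _median_iqr(dep)
    out["deprivation_index"]["missing"] = int(dep.isna().sum())

    if "initial_prescriber_specialty" in entries:
        spec = entries["initial_prescriber_specialty"]
        n_missing = int(spec.isna().sum())
        out["initial_prescriber"] = {
            "missing": n_missing,
            "levels": {
                s: {"n": int(c), "pct": percentage(int(c), n, n_missing)}
                for s, c in spec.value_counts().items()
            },
        }
    skip = {
        "patient_id", "index_drug", "entry_date", "age_at_entry", "sex",
        "deprivation_index", "initial_prescriber_specialty", "man",
        "n_episodes", "median_duration_days", "n_prescribers",
        "any_high_dose", "first_high_dose_midpoint",
    }
    flags = {}
    for c in entries.columns:
        if c in skip:
            continue
        v = entries[c]
        if set(v.dropna().unique()) <= {0, 1}:
            n_missing = int(v.isna().sum())
            flags[c] = {
                "n": int(v.sum()),
                "pct": percentage(float(v.sum()), n, n_missing),
                "missing": n_missing,
            }
    out["flags"] = flags
    for c in ("n_episodes", "median_duration_days", "n_prescribers"):
        if c in entries:
            out[c] = _median_iqr(entries[c])
    return out


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (dt.date, dt.datetime)):
            return o.isoformat()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (tuple, set)):
            return list(o)
        raise TypeError(type(o))

    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(GabadoseError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every index drug and sensitivity threshold.

    Returns the result bundle; all stage outputs are also written as
    CSV/JSON under ``config.output_dir``.  Deterministic given the inputs
    and config.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "started": dt.datetime.now().isoformat(timespec="seconds"),
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    def stage(name, fn, *args, **kwargs):
        try:
            log.info("stage %s", name)
            return fn(*args, **kwargs)
        except GabadoseError:
            raise
        except Exception as exc:  # annotate with the stage name
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(name, exc) from exc

    tables, validation_errors = stage("read_tables", read_tables, config)
    manifest["validation_errors"] = validation_errors
    manifest["inputs"] = {
        k: (len(v) if v is not None else 0) for k, v in tables.items()
    }

    tte_by_drug = {}
    for drug in config.drugs:
        ddir = outdir / drug
        ddir.mkdir(exist_ok=True)
        elig = dataclasses.replace(config.eligibility, index_drug=drug)
        entries, attrition = stage(
            f"{drug}/cohort",
            select_new_users,
            tables["dispensings"], tables["patients"], tables["enrolment"],
            tables["deaths"], elig,
        )
        entries = stage(
            f"{drug}/covariates",
            baseline_covariates,
            entries, tables["patients"], tables["dispensings"],
        )
        attrition.to_frame().to_csv(ddir / "attrition.csv", index=False)
        manifest["stages"][f"{drug}/cohort"] = len(entries)

        index_disp = tables["dispensings"].loc[
            tables["dispensings"]["drug"] == drug
        ]
        cohort_disp = index_disp.loc[
            index_disp["patient_id"].isin(entries["patient_id"])
        ]

        incidences = {}
        for threshold in config.sensitivity_thresholds:
            ep_cfg = dataclasses.replace(
                config.episodes, gap_threshold_days=threshold
            )
            # exposure starts at cohort entry: pre-entry dispensings (possible
            # under index-drug-only washout scopes) do not open episodes
            merged = cohort_disp.merge(
                entries[["patient_id", "entry_date"]], on="patient_id"
            )
            merged = merged.loc[
                pd.to_datetime(merged["date"]) >= pd.to_datetime(merged["entry_date"])
            ]
            episodes = stage(
                f"{drug}/episodes@{threshold}", build_episodes_table, merged, ep_cfg
            )
            summaries = exposure_summary(episodes, merged)
            tte = stage(
                f"{drug}/tte@{threshold}",
                derive_time_to_event,
                entries, summaries, tables["deaths"], tables["enrolment"],
                config.followup,
            )
            inc = incidence_rate(
                tte, days_per_year=config.followup.days_per_year
            )
            incidences[threshold] = inc.to_dict()
            km = kaplan_meier(tte)
            incidences[threshold]["cumulative_incidence_730d"] = float(
                km.incidence_at(config.followup.max_followup_days)
            )
            if threshold == config.episodes.gap_threshold_days:
                episodes.to_csv(ddir / "episodes.csv", index=False)
                tte.to_csv(ddir / "tte.csv", index=False)
                km.to_frame().to_csv(ddir / "km.csv", index=False)
                tte_by_drug[drug] = tte
                main_summaries = summaries
            manifest["stages"][f"{drug}/episodes@{threshold}"] = len(episodes)

        (ddir / "incidence.json").write_text(json.dumps(incidences, indent=2))
        results[f"{drug}/incidence"] = incidences

        entries = entries.merge(
            main_summaries.drop(columns=["drug"]), on="patient_id", how="left"
        )
        entries.to_csv(ddir / "cohort.csv", index=False)
        results[f"{drug}/entries"] = entries
        results[f"{drug}/attrition"] = attrition

        desc = stage(f"{drug}/describe", describe_cohort, entries)
        (ddir / "describe.json").write_text(json.dumps(desc, indent=2))
        results[f"{drug}/describe"] = desc

        cox_data = tte_by_drug[drug].merge(entries, on="patient_id").rename(
            columns={"age_at_entry": "age"}
        )
        fit = stage(f"{drug}/cox", fit_cox, cox_data, config.model)
        diag = stage(f"{drug}/ph_diagnostics", ph_diagnostics, fit)
        rep = report_factors(fit, diag)
        rep["forest"].to_csv(ddir / "factors.csv", index=False)
        curves = [
            df.assign(term=name) for name, df in rep["spline_curves"].items()
        ]
        if curves:
            pd.concat(curves).to_csv(ddir / "spline_curves.csv", index=False)
        cox_json = {
            "coefficients": fit.coefficients.to_dict(),
            "n_used": fit.n_used,
            "n_events": fit.n_events,
            "n_dropped_missing": fit.n_dropped_missing,
            "loglik": fit.loglik,
            "ph_global_chi_square": diag.global_chi_square,
            "ph_global_p": diag.global_p,
        }
        (ddir / "cox_results.json").write_text(json.dumps(cox_json, indent=2))
        results[f"{drug}/cox"] = fit
        results[f"{drug}/ph"] = diag
        manifest["stages"][f"{drug}/cox_terms"] = len(fit.coefficients)

        if tables["population"] is not None:
            series = stage(
                f"{drug}/trends", monthly_initiations, entries, tables["population"]
            )
            decomposed = stage(f"{drug}/stl", stl_trend, series)
            decomposed.to_csv(ddir / "trends.csv", index=False)
            results[f"{drug}/trends"] = decomposed

    if len(config.drugs) == 2:
        a, b = config.drugs
        chi2, p = stage("log_rank", log_rank, tte_by_drug[a], tte_by_drug[b])
        results["log_rank"] = {
            "chi_square": chi2, "p_value": p, "formatted": format_p(p)
        }
        (outdir / "log_rank.json").write_text(json.dumps(results["log_rank"]))

    manifest["finished"] = dt.datetime.now().isoformat(timespec="seconds")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
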