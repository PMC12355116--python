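"""Configuration objects for every pipeline stage.

All configs are plain dataclasses with eager validation: constructing an
invalid config raises :class:`~gabadose.errors.ConfigurationError` naming the
offending field.  Dates are ISO-8601 strings or ``datetime.date``; they are
normalised to ``datetime.date`` at construction.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError

DRUGS = ("pregabalin", "gabapentin")

#: WHO Defined Daily Dose, mg (assumed average maintenance dose per day).
DDD_MG = {"pregabalin": 300.0, "gabapentin": 1800.0}

#: Maximum recommended daily dose per summary of product characteristics, mg.
#: Equal to 2 DDD for both drugs; an average daily dose strictly above this
#: defines high-dose use.
MAX_RECOMMENDED_MG = {"pregabalin": 600.0, "gabapentin": 3600.0}

PRESCRIBER_SPECIALTIES = (
    "general_practitioner",
    "hospital_practitioner",
    "neurologist",
    "rheumatologist",
    "psychiatrist",
    "orthopaedic_surgeon",
    "other",
)


def _as_date(value, name: str) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigurationError(f"{name}: not an ISO-8601 date: {value!r}") from exc


def _check_prob(value, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name}: probability {value} outside [0, 1]")
    return value


def _check_nonneg(value, name: str) -> float:
    value = float(value)
    if value < 0:
        raise ConfigurationError(f"{name}: rate {value} must be >= 0")
    return value


@dataclass
class EligibilityConfig:
    """New-user inclusion/exclusion rules.

    A new user has ``min_dispensings`` dispensings of ``index_drug`` within
    ``qualification_window_days`` of the first one, none in the
    ``washout_days`` before it, is at least ``min_age_years`` old at entry,
    has known age and sex, and continuous enrolment over the washout year.
    """

    index_drug: str = "pregabalin"
    min_dispensings: int = 3
    qualification_window_days: int = 365
    washout_days: int = 365
    min_age_years: int = 18
    inclusion_start: dt.date = dt.date(2017, 1, 1)
    inclusion_end: dt.date = dt.date(2021, 12, 31)
    # index_drug_only: washout applies to the index drug only, so that prior
    # exposure to the other gabapentinoid remains a usable model covariate.
    washout_drug_scope: str = "index_drug_only"
    enrolment_gap_allowance_days: int = 0

    def __post_init__(self):
        if self.index_drug not in DRUGS:
            raise ConfigurationError(f"index_drug: unknown drug {self.index_drug!r}")
        if self.min_dispensings < 1:
            raise ConfigurationError("min_dispensings: must be >= 1")
        for name in ("qualification_window_days", "washout_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be > 0")
        self.inclusion_start = _as_date(self.inclusion_start, "inclusion_start")
        self.inclusion_end = _as_date(self.inclusion_end, "inclusion_end")
        if self.inclusion_start > self.inclusion_end:
            raise ConfigurationError("inclusion_start: must be <= inclusion_end")
        if self.washout_drug_scope not in ("index_drug_only", "both_gabapentinoids"):
            raise ConfigurationError(
                f"washout_drug_scope: unknown value {self.washout_drug_scope!r}"
            )


@dataclass
class EpisodeConfig:
    """Treatment-episode reconstruction parameters.

    A gap of more than ``gap_threshold_days`` between consecutive dispensings
    is a treatment interruption (default 35 = four weeks' maximum dispensing
    plus a one-week grace period; sensitivity values 42 and 56).  Every
    episode is extended by ``terminal_supply_days`` after its last dispensing
    so that single-dispensing episodes have a finite duration and the average
    daily dose is always defined.
    """

    gap_threshold_days: int = 35
    terminal_supply_days: int = 28
    ddd_mg: Mapping[str, float] = field(default_factory=lambda: dict(DDD_MG))
    max_recommended_mg: Mapping[str, float] = field(
        default_factory=lambda: dict(MAX_RECOMMENDED_MG)
    )

    def __post_init__(self):
        if self.gap_threshold_days <= 0:
            raise ConfigurationError("gap_threshold_days: must be > 0")
        if self.terminal_supply_days < 1:
            raise ConfigurationError("terminal_supply_days: must be >= 1")
        for drug, mg in self.ddd_mg.items():
            if mg <= 0:
                raise ConfigurationError(f"ddd_mg[{drug}]: must be > 0")
        for drug in self.max_recommended_mg:
            if drug not in self.ddd_mg:
                raise ConfigurationError(f"max_recommended_mg[{drug}]: no DDD defined")


@dataclass
class FollowupConfig:
    """Follow-up window and censoring order (death, then loss, then admin)."""

    max_followup_days: int = 730
    censoring_priority: Sequence[str] = ("death", "loss", "admin")
    days_per_year: float = 365.25

    def __post_init__(self):
        if self.max_followup_days <= 0:
            raise ConfigurationError("max_followup_days: must be > 0")
        if sorted(self.censoring_priority) != ["admin", "death", "loss"]:
            raise ConfigurationError(
                "censoring_priority: must be a permutation of death/loss/admin"
            )


@dataclass
class ModelSpec:
    """Cox model specification: which covariates enter and how."""

    binary_covariates: Sequence[str] = (
        "man",
        "prior_other_gabapentinoid",
        "opioid_agonist_treatments",
        "strong_opioid_analgesics",
        "paraplegia",
        "active_cancers",
        "diabetes",
        "substance_use_disorders",
        "epilepsy",
    )
    categorical_covariates: Mapping[str, str] = field(
        default_factory=lambda: {"initial_prescriber_specialty": "general_practitioner"}
    )
    spline_covariates: Mapping[str, int] = field(
        default_factory=lambda: {"age": 5, "deprivation_index": 5, "n_prescribers": 5}
    )
    ties_method: str = "efron"
    variance: str = "robust"
    missing_policy: str = "complete_case"

    def __post_init__(self):
        if self.ties_method not in ("efron", "breslow"):
            raise ConfigurationError(f"ties_method: unknown {self.ties_method!r}")
        if self.variance not in ("robust", "model_based"):
            raise ConfigurationError(f"variance: unknown {self.variance!r}")
        if self.missing_policy != "complete_case":
            raise ConfigurationError("missing_policy: only complete_case is supported")
        for name, df in self.spline_covariates.items():
            if df < 3:
                raise ConfigurationError(f"spline_covariates[{name}]: df must be >= 3")


@dataclass
class DoseRegime:
    """Lognormal daily-dose regime in DDD units.

    ``median_ddd`` and ``sigma`` parameterise a lognormal; ``shift_ddd`` is
    added after sampling (used to keep high-dose regimes strictly above
    2 DDD); ``cap_ddd`` truncates from above (used to keep therapeutic
    regimes strictly below 2 DDD).
    """

    median_ddd: float
    sigma: float
    shift_ddd: float = 0.0
    cap_ddd: float | None = None


@dataclass
class SimulationConfig:
    """Ground-truth generator configuration.

    Defaults encode the study conditions: a 2017–2021 inclusion window, a
    covariate mix and cohort structure near the published baseline table, and
    an exponential proportional-hazards event process whose default log
    hazard ratios are the published pregabalin-cohort estimates.
    """

    n_patients: int = 10_000
    seed: int = 0
    study_start: dt.date = dt.date(2017, 1, 1)
    study_end: dt.date = dt.date(2021, 12, 31)

    #: share of patients initiating pregabalin (the rest initiate gabapentin)
    pregabalin_share: float = 0.768
    #: probability of >=1 dispensing of the other gabapentinoid in the
    #: washout year, by index drug
    prior_other_exposure: Mapping[str, float] = field(
        default_factory=lambda: {"pregabalin": 0.044, "gabapentin": 0.290}
    )
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "opioid_agonist_treatments": 0.007,
            "strong_opioid_analgesics": 0.127,
            "paraplegia": 0.014,
            "active_cancers": 0.118,
            "diabetes": 0.221,
            "substance_use_disorders": 0.045,
            "epilepsy": 0.021,
        }
    )
    #: age ~ Normal(loc, scale) truncated to [18, 100]; defaults give
    #: median 64, IQR ~[52, 76]
    age_loc: float = 64.0
    age_scale: float = 17.8
    sex_ratio_women: float = 0.577
    deprivation_loc: float = 0.4
    deprivation_scale: float = 1.5

    #: ground-truth log hazard ratios (binary flags plus the derived
    #: man / prior_other_gabapentinoid indicators; optional continuous keys
    #: "age" and "deprivation_index" are per-unit effects centred at the
    #: population medians)
    true_log_hrs: Mapping[str, float] = field(
        default_factory=lambda: {
            "man": 0.5128236264286637,  # ln 1.67
            "opioid_agonist_treatments": 1.1939224684724346,  # ln 3.30
            "paraplegia": 0.6626879748184737,  # ln 1.94
            "prior_other_gabapentinoid": 0.6523251860396900,  # ln 1.92
            "active_cancers": 0.2776317365982795,  # ln 1.32
            "strong_opioid_analgesics": 0.2390169004705471,  # ln 1.27
        }
    )
    #: events per person-year for a reference patient (all flags 0), by drug
    baseline_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"pregabalin": 0.0176, "gabapentin": 0.0057}
    )

    refill_gap_mean_days: float = 26.5
    refill_gap_jitter_days: float = 8.5  # gaps uniform on mean +/- jitter
    episodes_per_patient_mean_extra: float = 3.2  # n_episodes ~ 1 + Poisson
    dispensings_per_episode_mean_extra: float = 1.1  # n_disp ~ 1 + Poisson
    inter_episode_gap_range: tuple[int, int] = (45, 130)

    dose_regimes: Mapping[str, Mapping[str, DoseRegime]] = field(
        default_factory=lambda: {
            "pregabalin": {
                "therapeutic": DoseRegime(0.80, 0.35, cap_ddd=1.8),
                "high_dose": DoseRegime(0.35, 0.70, shift_ddd=2.05),
            },
            "gabapentin": {
                "therapeutic": DoseRegime(0.75, 0.35, cap_ddd=1.8),
                "high_dose": DoseRegime(0.25, 0.40, shift_ddd=2.05),
            },
        }
    )

    death_rate_py: float = 0.030
    loss_rate_py: float = 0.015
    #: fraction of patients with no recorded deprivation index / prescriber
    #: specialty (present in the data but missing-at-random, as in claims)
    deprivation_missing_fraction: float = 0.057
    prescriber_missing_fraction: float = 0.030

    edge_case_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "prevalent": 0.06,
            "occasional": 0.06,
            "minor": 0.01,
            "missing_demographics": 0.01,
            "enrolment_gap": 0.02,
        }
    )

    #: monthly initiation trend: piecewise-linear relative weights per drug,
    #: as (month_index, weight) breakpoints over the inclusion window, plus a
    #: sinusoidal seasonal modulation
    trend_breakpoints: Mapping[str, Sequence[tuple[int, float]]] = field(
        default_factory=lambda: {
            "pregabalin": [(0, 1.00), (36, 1.05), (59, 0.63)],
            "gabapentin": [(0, 0.90), (36, 0.92), (59, 1.45)],
        }
    )
    seasonal_amplitude: float = 0.05

    #: population denominator for the trends module (grows linearly)
    population_start: int = 66_800_000
    population_monthly_growth: int = 10_000

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigurationError("n_patients: must be >= 0")
        self.study_start = _as_date(self.study_start, "study_start")
        self.study_end = _as_date(self.study_end, "study_end")
        if self.study_start >= self.study_end:
            raise ConfigurationError("study_start: must be < study_end")
        _check_prob(self.pregabalin_share, "pregabalin_share")
        _check_prob(self.sex_ratio_women, "sex_ratio_women")
        for name, p in {**self.prior_other_exposure}.items():
            _check_prob(p, f"prior_other_exposure[{name}]")
        for name, p in self.covariate_prevalences.items():
            _check_prob(p, f"covariate_prevalences[{name}]")
        for name, p in self.edge_case_fractions.items():
            _check_prob(p, f"edge_case_fractions[{name}]")
        if sum(self.edge_case_fractions.values()) > 1.0:
            raise ConfigurationError("edge_case_fractions: fractions sum to > 1")
        for name in ("death_rate_py", "loss_rate_py"):
            _check_nonneg(getattr(self, name), name)
        for drug, h in self.baseline_hazard.items():
            _check_nonneg(h, f"baseline_hazard[{drug}]")
        known = set(self.covariate_prevalences) | {
            "man",
            "prior_other_gabapentinoid",
            "age",
            "deprivation_index",
        }
        for name in self.true_log_hrs:
            if name not in known:
                raise ConfigurationError(
                    f"true_log_hrs[{name}]: not a known covariate"
                )
        if self.refill_gap_mean_days - self.refill_gap_jitter_days <= 0:
            raise ConfigurationError("refill_gap_jitter_days: jitter >= mean gap")

    @property
    def data_end(self) -> dt.date:
        """Last calendar date with recorded data: inclusion end + 2 years of
        follow-up."""
        return self.study_end + dt.timedelta(days=730)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (paths + per-stage configs)."""

    patients_path: str = "patients.csv"
    dispensings_path: str = "dispensings.csv"
    enrolment_path: str = "enrolment.csv"
    deaths_path: str = "deaths.csv"
    population_path: str = "population.csv"
    output_dir: str = "output"
    seed: int = 0
    drugs: Sequence[str] = DRUGS
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    episodes: EpisodeConfig = field(default_factory=EpisodeConfig)
    followup: FollowupConfig = field(default_factory=FollowupConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    sensitivity_thresholds: Sequence[int] = (35, 42, 56)

    def __post_init__(self):
        if self.episodes.gap_threshold_days not in self.sensitivity_thresholds:
            raise ConfigurationError(
                "sensitivity_thresholds: must include the main gap threshold"
            )
        for drug in self.drugs:
            if drug not in DRUGS:
                raise ConfigurationError(f"drugs: unknown drug {drug!r}")


def _from_mapping(cls, data: Mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"{cls.__name__}: unknown field(s) {sorted(unknown)}"
        )
    return cls(**data)


def pipeline_config_from_dict(data: Mapping) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a nested plain-dict (YAML) form."""
    data = dict(data)
    for key, cls in (
        ("eligibility", EligibilityConfig),
        ("episodes", EpisodeConfig),
        ("followup", FollowupConfig),
        ("model", ModelSpec),
    ):
        if key in data and isinstance(data[key], Mapping):
            data[key] = _from_mapping(cls, data[key])
    return _from_mapping(PipelineConfig, data)


def load_pipeline_config(path: str) -> PipelineConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(data)
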