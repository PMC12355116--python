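"""Synthetic claims-data generator with a known proportional-hazards truth.

The generator emulates a national pharmacy-claims extract: per-patient
dispensing streams of pregabalin/gabapentin with a ~28-day refill cadence,
demographics, comorbidity flags, enrolment intervals and deaths.  Each
patient carries a latent high-dose event time drawn from an exponential
proportional-hazards model,

    rate_i = baseline_hazard[drug] * exp(sum_j beta_j * z_ij),

which is then *expressed* in the dispensing stream as one treatment episode
whose reconstructed average daily dose exceeds 2 DDD and whose midpoint
lands on the latent event time.  Because the event mechanism instantiates
exactly the model the analysis fits, parameter recovery through the full
cohort -> episodes -> time-to-event -> Cox chain is well-posed.

Ineligible records (prevalent users with pre-window dispensing chains,
occasional users, minors, missing demographics, enrolment gaps) are injected
at configurable fractions so the cohort builder's exclusion rules are
exercised with known ground truth.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DDD_MG, DRUGS, SimulationConfig
from .errors import DataError

ELIGIBILITY_LABELS = (
    "eligible",
    "prevalent",
    "occasional",
    "minor",
    "missing_demographics",
    "enrolment_gap",
)

# labels whose patients carry a full, qualifying dispensing stream
_FULL_STREAM = ("eligible", "prevalent", "minor", "missing_demographics", "enrolment_gap")

#: initial-prescriber specialty mix (probabilities among recorded values)
SPECIALTY_PROBS = {
    "pregabalin": {
        "general_practitioner": 0.631,
        "hospital_practitioner": 0.148,
        "neurologist": 0.039,
        "rheumatologist": 0.047,
        "psychiatrist": 0.020,
        "orthopaedic_surgeon": 0.018,
        "other": 0.097,
    },
    "gabapentin": {
        "general_practitioner": 0.513,
        "hospital_practitioner": 0.186,
        "neurologist": 0.112,
        "rheumatologist": 0.044,
        "psychiatrist": 0.011,
        "orthopaedic_surgeon": 0.016,
        "other": 0.118,
    },
}


def _month_starts(config: SimulationConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.study_start, config.study_end, freq="MS")


def month_weights(config: SimulationConfig, drug: str) -> np.ndarray:
    """Relative initiation weight per calendar month of the inclusion window:
    piecewise-linear trend times a sinusoidal seasonal factor."""
    months = _month_starts(config)
    m = np.arange(len(months))
    bp = config.trend_breakpoints[drug]
    xs = np.array([b[0] for b in bp], dtype=float)
    ys = np.array([b[1] for b in bp], dtype=float)
    trend = np.interp(m, xs, ys)
    seasonal = 1.0 + config.seasonal_amplitude * np.sin(2 * np.pi * m / 12.0)
    w = trend * seasonal
    return w / w.sum()


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Draw the ground-truth patient population.

    Returns one row per patient: identifiers, eligibility label, index drug,
    intended entry date, demographics, covariate flags, the latent event /
    death / loss times (days since entry; event time may be ``inf``) and the
    true linear predictor.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cols: dict = {"patient_id": np.arange(1, n + 1)}
    if n == 0:
        df = pd.DataFrame(cols)
        for c in _POPULATION_EXTRA_COLS + sorted(config.covariate_prevalences):
            df[c] = pd.Series(dtype=float)
        return df

    # eligibility labels
    fracs = config.edge_case_fractions
    labels = np.array(ELIGIBILITY_LABELS)
    probs = np.array(
        [1.0 - sum(fracs.values())] + [fracs[lab] for lab in labels[1:]]
    )
    label = rng.choice(labels, size=n, p=probs)

    drug = np.where(
        rng.random(n) < config.pregabalin_share, "pregabalin", "gabapentin"
    )

    # entry dates from the per-drug monthly trend
    months = _month_starts(config)
    month_len = np.asarray(months.days_in_month)
    entry_day = np.empty(n, dtype=int)
    month_off = (months - pd.Timestamp(config.study_start)).days.to_numpy()
    for d in DRUGS:
        mask = drug == d
        mi = rng.choice(len(months), size=mask.sum(), p=month_weights(config, d))
        entry_day[mask] = month_off[mi] + rng.integers(0, month_len[mi])

    # demographics
    from scipy.stats import truncnorm

    a = (18 - config.age_loc) / config.age_scale
    b = (100 - config.age_loc) / config.age_scale
    age = np.round(
        truncnorm.rvs(a, b, loc=config.age_loc, scale=config.age_scale,
                      size=n, random_state=rng)
    ).astype(int)
    age[label == "minor"] = rng.integers(12, 18, size=(label == "minor").sum())
    sex = np.where(rng.random(n) < config.sex_ratio_women, "woman", "man")
    deprivation = rng.normal(config.deprivation_loc, config.deprivation_scale, n)
    deprivation_missing = rng.random(n) < config.deprivation_missing_fraction

    covs = {}
    for name in sorted(config.covariate_prevalences):
        covs[name] = (rng.random(n) < config.covariate_prevalences[name]).astype(int)
    prior_p = np.array([config.prior_other_exposure[d] for d in drug])
    prior_other = (rng.random(n) < prior_p).astype(int)

    # latent event process: exponential PH
    lp = np.zeros(n)
    for name, beta in config.true_log_hrs.items():
        if name == "man":
            lp += beta * (sex == "man")
        elif name == "prior_other_gabapentinoid":
            lp += beta * prior_other
        elif name == "age":
            lp += beta * (age - config.age_loc)
        elif name == "deprivation_index":
            lp += beta * (deprivation - config.deprivation_loc)
        else:
            lp += beta * covs[name]
    base = np.array([config.baseline_hazard[d] for d in drug]) / 365.25
    rate = base * np.exp(lp)
    with np.errstate(divide="ignore"):
        latent = np.where(rate > 0, rng.exponential(1.0, n) / np.where(rate > 0, rate, 1.0), np.inf)

    death = (
        rng.exponential(1.0, n) / (config.death_rate_py / 365.25)
        if config.death_rate_py > 0
        else np.full(n, np.inf)
    )
    loss = (
        rng.exponential(1.0, n) / (config.loss_rate_py / 365.25)
        if config.loss_rate_py > 0
        else np.full(n, np.inf)
    )

    missing_sex = np.zeros(n, dtype=bool)
    missing_age = np.zeros(n, dtype=bool)
    md = label == "missing_demographics"
    which = rng.integers(0, 3, size=n)  # 0: sex, 1: age, 2: both
    missing_sex[md & (which != 1)] = True
    missing_age[md & (which != 0)] = True

    df = pd.DataFrame(
        {
            "patient_id": cols["patient_id"],
            "eligibility_label": label,
            "drug": drug,
            "entry_day": entry_day,
            "age_at_entry": age,
            "sex": sex,
            "missing_sex": missing_sex,
            "missing_age": missing_age,
            "deprivation_index": deprivation,
            "deprivation_missing": deprivation_missing,
            "prior_other_gabapentinoid": prior_other,
            "latent_event_time": latent,
            "death_time": death,
            "loss_time": loss,
            "linear_predictor": lp,
        }
    )
    for name, v in covs.items():
        df[name] = v
    start = pd.Timestamp(config.study_start)
    df["intended_entry_date"] = start + pd.to_timedelta(df["entry_day"], unit="D")
    return df


_POPULATION_EXTRA_COLS = [
    "eligibility_label",
    "drug",
    "entry_day",
    "age_at_entry",
    "sex",
    "missing_sex",
    "missing_age",
    "deprivation_index",
    "deprivation_missing",
    "prior_other_gabapentinoid",
    "latent_event_time",
    "death_time",
    "loss_time",
    "linear_predictor",
    "intended_entry_date",
]


def _sample_dose_ddd(rng, regime) -> float:
    v = rng.lognormal(np.log(regime.median_ddd), regime.sigma) + regime.shift_ddd
    if regime.cap_ddd is not None:
        v = min(v, regime.cap_ddd)
    return v


def _hd_episode_days(rng, T, gmin, gmax, terminal):
    """Relative dispensing days and start for the high-dose episode so that
    start + floor(duration/2) == T, with all internal gaps <= gmax."""
    nd = 1 + rng.poisson(1.5)
    if nd > 1:
        rel = np.concatenate(([0], np.cumsum(rng.integers(gmin, gmax + 1, nd - 1))))
    else:
        rel = np.array([0])
    dur = rel[-1] + terminal
    start = T - dur // 2
    return start, rel


def _day0_hd_days(T, terminal, gmax):
    """High-dose episode anchored at day 0 with midpoint ~= T."""
    span = max(0, 2 * T - terminal)
    if span == 0:
        return np.array([0])
    nd = int(np.ceil(span / (gmax - 7))) + 1  # spacing well under the threshold
    return np.round(np.linspace(0, span, nd)).astype(int)


def generate_dispensings(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    *,
    with_profiles: bool = False,
):
    """Build the per-patient dispensing streams expressing the ground truth.

    Eligible-type patients receive a multi-episode stream anchored at their
    entry date; a finite latent event time before censoring is expressed as a
    high-dose episode centred on it.  Prevalent users additionally carry a
    monthly dispensing chain reaching back before the inclusion window;
    occasional users get at most two dispensings.  Patients whose drawn
    death/loss truncates the stream below the qualifying three dispensings
    are relabelled ``occasional`` (their realised record genuinely is).

    With ``with_profiles=True`` also returns the updated profile table with
    the realised labels and the expressed event day.
    """
    unknown = set(profiles["drug"].unique()) - set(DRUGS) if len(profiles) else set()
    if unknown:
        raise DataError(f"profile references unknown drug(s): {sorted(unknown)}")

    rng = np.random.default_rng([config.seed, 1])
    gmin = int(config.refill_gap_mean_days - config.refill_gap_jitter_days)
    gmax = int(config.refill_gap_mean_days + config.refill_gap_jitter_days)
    ig_lo, ig_hi = config.inter_episode_gap_range
    terminal = 28
    horizon_abs = (config.data_end - config.study_start).days

    out_pid, out_drug, out_day, out_qty, out_presc, out_spec = [], [], [], [], [], []
    new_label = profiles["eligibility_label"].to_numpy(copy=True).astype(object)
    expressed = np.full(len(profiles), np.nan)

    spec_names = {d: list(SPECIALTY_PROBS[d]) for d in DRUGS}
    spec_probs = {
        d: np.array(list(SPECIALTY_PROBS[d].values()))
        / sum(SPECIALTY_PROBS[d].values())
        for d in DRUGS
    }

    rows = profiles.reset_index(drop=True)
    n = len(rows)
    n_ep_base = 1 + rng.poisson(config.episodes_per_patient_mean_extra, size=max(n, 1))
    pool_sizes = 1 + np.minimum(rng.poisson(0.8, size=max(n, 1)), 7)

    pid_a = rows["patient_id"].to_numpy() if n else np.array([], dtype=int)
    drug_a = rows["drug"].to_numpy() if n else np.array([], dtype=object)
    entry_a = rows["entry_day"].to_numpy(dtype=int) if n else np.array([], dtype=int)
    death_a = rows["death_time"].to_numpy() if n else np.array([])
    loss_a = rows["loss_time"].to_numpy() if n else np.array([])
    latent_a = rows["latent_event_time"].to_numpy() if n else np.array([])
    prior_a = rows["prior_other_gabapentinoid"].to_numpy() if n else np.array([])

    for i in range(n):
        label = new_label[i]
        drug = drug_a[i]
        entry = int(entry_a[i])
        horizon = horizon_abs - entry
        stop = min(death_a[i], loss_a[i], horizon)
        regimes = config.dose_regimes[drug]

        pool = rng.integers(100_000, 1_000_000, size=pool_sizes[i])
        pool_spec = rng.choice(spec_names[drug], size=pool_sizes[i], p=spec_probs[drug])
        spec_missing = rng.random(pool_sizes[i]) < config.prescriber_missing_fraction

        episodes: list[tuple[int, np.ndarray, str]] = []  # (start, rel days, regime)

        if label == "occasional":
            nd = rng.integers(1, 3)
            rel = (
                np.concatenate(([0], np.cumsum(rng.integers(gmin, gmax + 1, nd - 1))))
                if nd > 1
                else np.array([0])
            )
            episodes.append((0, rel, "therapeutic"))
        else:
            T = latent_a[i]
            express = np.isfinite(T) and 1 <= round(T) < min(stop, 730)
            Ti = int(round(T)) if express else None

            n_ep = int(n_ep_base[i]) + (1 if express else 0)
            specs = []
            for _ in range(n_ep):
                nd = 1 + rng.poisson(config.dispensings_per_episode_mean_extra)
                rel = (
                    np.concatenate(
                        ([0], np.cumsum(rng.integers(gmin, gmax + 1, nd - 1)))
                    )
                    if nd > 1
                    else np.array([0])
                )
                specs.append(rel)
            starts = []
            cur = 0
            for rel in specs:
                starts.append(cur)
                cur = cur + int(rel[-1]) + int(rng.integers(ig_lo, ig_hi + 1))

            if express:
                s_hd, rel_hd = _hd_episode_days(rng, Ti, gmin, gmax, terminal)
                ep1_last = starts[0] + int(specs[0][-1])
                if s_hd >= 36 and ep1_last + 36 <= s_hd:
                    before = [
                        (s, r)
                        for s, r in zip(starts, specs)
                        if s + int(r[-1]) + 36 <= s_hd
                    ]
                    after = [
                        r for s, r in zip(starts, specs) if s + int(r[-1]) + 36 > s_hd
                    ]
                else:
                    rel_hd = _day0_hd_days(Ti, terminal, gmax)
                    s_hd = 0
                    before, after = [], specs
                episodes.extend((s, r, "therapeutic") for s, r in before)
                episodes.append((s_hd, rel_hd, "high_dose"))
                cur = s_hd + int(rel_hd[-1]) + int(rng.integers(ig_lo, ig_hi + 1))
                for rel in after:
                    episodes.append((cur, rel, "therapeutic"))
                    cur = cur + int(rel[-1]) + int(rng.integers(ig_lo, ig_hi + 1))
            else:
                episodes.extend((s, r, "therapeutic") for s, r in zip(starts, specs))

        # truncate at death/loss/data end
        kept = []
        for s, rel, reg in episodes:
            days = s + rel
            days = days[days <= stop]
            if len(days):
                kept.append((days, reg))
        episodes = kept

        # guarantee the qualifying >=3 dispensings in the first 365 days
        if label in _FULL_STREAM and episodes:
            all_days = np.concatenate([d for d, _ in episodes])
            n365 = int((all_days <= 365).sum())
            if n365 < 3:
                days0, reg0 = episodes[0]
                nxt = episodes[1][0][0] if len(episodes) > 1 else np.inf
                extra = []
                day = int(days0[-1])
                while n365 + len(extra) < 3:
                    day += gmin
                    if day > min(stop, 365) or day + 36 > nxt:
                        break
                    extra.append(day)
                if n365 + len(extra) >= 3:
                    episodes[0] = (np.concatenate([days0, extra]).astype(int), reg0)
                elif label == "eligible":
                    new_label[i] = "occasional"
                    keep2 = np.sort(all_days)[:2]
                    episodes = [(keep2, "therapeutic")]

        # emit dispensings with doses
        ddd_mg = DDD_MG[drug]
        for days, reg in episodes:
            dose_ddd = _sample_dose_ddd(rng, regimes[reg])
            duration = int(days[-1] - days[0]) + terminal
            total_mg = dose_ddd * ddd_mg * duration
            qty = round(total_mg / len(days), 2)
            idx = rng.integers(0, pool_sizes[i], size=len(days))
            for d, j in zip(days, idx):
                out_pid.append(pid_a[i])
                out_drug.append(drug)
                out_day.append(entry + int(d))
                out_qty.append(qty)
                out_presc.append(pool[j])
                out_spec.append(None if spec_missing[j] else pool_spec[j])
            if reg == "high_dose":
                expressed[i] = days[0] + (int(days[-1] - days[0]) + terminal) // 2

        # prevalent users: monthly chain reaching back before the window
        if label == "prevalent":
            chain = np.arange(-30, -(entry + 61), -30)
            dose_ddd = _sample_dose_ddd(rng, regimes["therapeutic"])
            qty = round(dose_ddd * ddd_mg * 30, 2)
            idx = rng.integers(0, pool_sizes[i], size=len(chain))
            for d, j in zip(chain, idx):
                out_pid.append(pid_a[i])
                out_drug.append(drug)
                out_day.append(entry + int(d))
                out_qty.append(qty)
                out_presc.append(pool[j])
                out_spec.append(None if spec_missing[j] else pool_spec[j])

        # prior exposure to the other gabapentinoid, inside the washout year
        if prior_a[i] == 1:
            other = "gabapentin" if drug == "pregabalin" else "pregabalin"
            d = -int(rng.integers(30, 331))
            dose_ddd = _sample_dose_ddd(rng, config.dose_regimes[other]["therapeutic"])
            out_pid.append(pid_a[i])
            out_drug.append(other)
            out_day.append(entry + d)
            out_qty.append(round(dose_ddd * DDD_MG[other] * 28, 2))
            out_presc.append(pool[0])
            out_spec.append(None if spec_missing[0] else pool_spec[0])

    start = pd.Timestamp(config.study_start)
    disp = pd.DataFrame(
        {
            "patient_id": pd.array(out_pid, dtype="int64"),
            "drug": out_drug,
            "date": start + pd.to_timedelta(out_day, unit="D"),
            "quantity_mg": out_qty,
            "prescriber_id": pd.array(out_presc, dtype="int64"),
            "prescriber_specialty": out_spec,
        }
    )
    disp = disp.sort_values(["patient_id", "drug", "date"], kind="mergesort").reset_index(
        drop=True
    )
    if not with_profiles:
        return disp
    updated = rows.copy()
    updated["eligibility_label"] = new_label
    updated["expressed_event_day"] = expressed
    return disp, updated


def build_tables(profiles: pd.DataFrame, config: SimulationConfig) -> dict:
    """Assemble the patients / enrolment / deaths / population tables."""
    start = pd.Timestamp(config.study_start)
    horizon_abs = (config.data_end - config.study_start).days
    rng = np.random.default_rng([config.seed, 2])
    n = len(profiles)

    entry_year = (start + pd.to_timedelta(profiles["entry_day"], unit="D")).dt.year
    birth_year = entry_year - profiles["age_at_entry"]
    patients = pd.DataFrame(
        {
            "patient_id": profiles["patient_id"],
            "birth_year": birth_year.astype("Int64"),
            "sex": profiles["sex"].astype(object),
            "deprivation_index": profiles["deprivation_index"],
        }
    )
    patients.loc[profiles["missing_age"].to_numpy(), "birth_year"] = pd.NA
    patients.loc[profiles["missing_sex"].to_numpy(), "sex"] = None
    patients.loc[profiles["deprivation_missing"].to_numpy(), "deprivation_index"] = np.nan
    for name in sorted(config.covariate_prevalences):
        patients[name] = profiles[name].astype(int)

    # enrolment: one interval per patient; loss to follow-up is expressed as
    # an early interval end; enrolment-gap patients get a hole in the washout
    enr_start = profiles["entry_day"].to_numpy() - rng.integers(400, 3001, size=max(n, 1))[:n]
    loss = profiles["loss_time"].to_numpy()
    entry = profiles["entry_day"].to_numpy()
    horizon = horizon_abs - entry
    end_rel = np.where(np.isfinite(loss), np.minimum(loss, horizon), horizon)
    end_abs = entry + np.floor(end_rel).astype(int)

    pid, s_list, e_list = [], [], []
    gap_mask = (profiles["eligibility_label"] == "enrolment_gap").to_numpy()
    for i in range(n):
        p = profiles["patient_id"].iloc[i]
        if gap_mask[i]:
            pid += [p, p]
            s_list += [enr_start[i], entry[i] - 100]
            e_list += [entry[i] - 200, end_abs[i]]
        else:
            pid.append(p)
            s_list.append(enr_start[i])
            e_list.append(end_abs[i])
    enrolment = pd.DataFrame(
        {
            "patient_id": pd.array(pid, dtype="int64"),
            "start_date": start + pd.to_timedelta(s_list, unit="D"),
            "end_date": start + pd.to_timedelta(e_list, unit="D"),
        }
    )

    death = profiles["death_time"].to_numpy()
    has_death = np.isfinite(death) & (death <= horizon)
    deaths = pd.DataFrame(
        {
            "patient_id": profiles.loc[has_death, "patient_id"],
            "death_date": start
            + pd.to_timedelta(
                entry[has_death] + np.floor(death[has_death]).astype(int), unit="D"
            ),
        }
    ).reset_index(drop=True)

    months = _month_starts(config)
    population = pd.DataFrame(
        {
            "month": months.strftime("%Y-%m"),
            "population": config.population_start
            + config.population_monthly_growth * np.arange(len(months)),
        }
    )
    return {
        "patients": patients,
        "enrolment": enrolment,
        "deaths": deaths,
        "population": population,
    }


def write_truth_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth table keyed by patient_id — for tests only, never read by
    the analysis pipeline."""
    if len(profiles) == 0:
        return pd.DataFrame(columns=["patient_id"] + _POPULATION_EXTRA_COLS)
    cols = ["patient_id"] + [c for c in profiles.columns if c != "patient_id"]
    return profiles[cols].set_index("patient_id").reset_index()


def simulate_dataset(config: SimulationConfig, output_dir: str | Path) -> dict:
    """Run the full generator and write the delimited text tables.

    Writes ``patients.csv``, ``dispensings.csv``, ``enrolment.csv``,
    ``deaths.csv``, ``population.csv`` and the test-only ``truth.csv`` to
    ``output_dir``; returns the tables as DataFrames.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    profiles = generate_population(config)
    dispensings, profiles = generate_dispensings(profiles, config, with_profiles=True)
    tables = build_tables(profiles, config)
    tables["dispensings"] = dispensings
    tables["truth"] = write_truth_table(profiles)

    def _w(name, df, date_cols=()):
        df = df.copy()
        for c in date_cols:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        df.to_csv(output_dir / f"{name}.csv", index=False)

    _w("patients", tables["patients"])
    _w("dispensings", tables["dispensings"], ["date"])
    _w("enrolment", tables["enrolment"], ["start_date", "end_date"])
    _w("deaths", tables["deaths"], ["death_date"])
    _w("population", tables["population"])
    _w("truth", tables["truth"], ["intended_entry_date"])
    return tables
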