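"""Treatment-episode reconstruction from dispensing dates.

Claims data record when a drug was dispensed but not the prescribed regimen
or days' supply, so exposure has to be reconstructed from the dispensing
stream itself.  A *treatment episode* is a maximal run of dispensings in
which consecutive dispensings are separated by at most ``gap_threshold_days``
(default 35 = the four-week maximum dispensing period plus a one-week grace
period); a longer gap is a treatment interruption and the next dispensing
opens a new episode.

The average daily dose over an episode is the total quantity dispensed in it
divided by the episode duration.  Duration runs from the first dispensing to
``terminal_supply_days`` (default 28) past the last one, so single-dispensing
episodes cover one supply period rather than zero days.  Doses are expressed
both in mg/day and in Defined Daily Doses (DDD; pregabalin 300 mg,
gabapentin 1800 mg).  An episode is *high-dose* when its average daily dose
strictly exceeds the maximum recommended dose (600 mg pregabalin, 3600 mg
gabapentin — 2 DDD for both).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EpisodeConfig
from .errors import ConfigurationError, DataError

EPISODE_COLUMNS = [
    "patient_id",
    "drug",
    "start_date",
    "last_dispensing_date",
    "duration_days",
    "total_mg",
    "avg_daily_dose_mg",
    "avg_daily_dose_ddd",
    "n_dispensings",
    "high_dose",
    "midpoint_date",
]


def _validate(dispensings: pd.DataFrame, config: EpisodeConfig) -> None:
    if (dispensings["quantity_mg"] <= 0).any():
        bad = dispensings.loc[dispensings["quantity_mg"] <= 0].iloc[0]
        raise DataError(
            f"non-positive quantity_mg {bad['quantity_mg']} for patient "
            f"{bad['patient_id']} on {bad['date']}"
        )
    unknown = set(dispensings["drug"].unique()) - set(config.ddd_mg)
    if unknown:
        raise ConfigurationError(f"no DDD configured for drug(s) {sorted(unknown)}")


def build_episodes_table(
    dispensings: pd.DataFrame, config: EpisodeConfig | None = None
) -> pd.DataFrame:
    """Segment a dispensing table into treatment episodes.

    Parameters
    ----------
    dispensings
        Columns ``patient_id``, ``drug``, ``date`` (datetime-like),
        ``quantity_mg``.  May cover many patients and both drugs; episodes
        are built independently per (patient, drug).  Same-day rows are
        summed into a single day's quantity.
    config
        Episode reconstruction parameters.

    Returns
    -------
    DataFrame with one row per episode (columns :data:`EPISODE_COLUMNS`),
    sorted by patient, drug, start date.
    """
    config = config or EpisodeConfig()
    if len(dispensings) == 0:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    _validate(dispensings, config)

    df = dispensings[["patient_id", "drug", "date", "quantity_mg"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    # same-day duplicates: one dispensing split across rows
    df = (
        df.groupby(["patient_id", "drug", "date"], as_index=False, sort=False)[
            "quantity_mg"
        ]
        .sum()
        .sort_values(["patient_id", "drug", "date"], kind="mergesort")
        .reset_index(drop=True)
    )

    same_group = (df["patient_id"] == df["patient_id"].shift()) & (
        df["drug"] == df["drug"].shift()
    )
    gap = (df["date"] - df["date"].shift()).dt.days
    new_episode = ~same_group | (gap > config.gap_threshold_days)
    episode_id = new_episode.cumsum()

    grouped = df.groupby(episode_id, sort=True)
    out = grouped.agg(
        patient_id=("patient_id", "first"),
        drug=("drug", "first"),
        start_date=("date", "min"),
        last_dispensing_date=("date", "max"),
        total_mg=("quantity_mg", "sum"),
        n_dispensings=("quantity_mg", "size"),
    ).reset_index(drop=True)

    span = (out["last_dispensing_date"] - out["start_date"]).dt.days
    out["duration_days"] = span + config.terminal_supply_days
    out["avg_daily_dose_mg"] = out["total_mg"] / out["duration_days"]
    ddd = out["drug"].map(config.ddd_mg).astype(float)
    out["avg_daily_dose_ddd"] = out["avg_daily_dose_mg"] / ddd
    maxmg = out["drug"].map(config.max_recommended_mg).astype(float)
    out["high_dose"] = out["avg_daily_dose_mg"] > maxmg
    out["midpoint_date"] = out["start_date"] + pd.to_timedelta(
        np.floor(out["duration_days"] / 2).astype(int), unit="D"
    )
    return out[EPISODE_COLUMNS]


def build_episodes(
    dispensings: pd.DataFrame, config: EpisodeConfig | None = None
) -> pd.DataFrame:
    """Episodes for a single patient and drug (thin wrapper over
    :func:`build_episodes_table` that enforces the single-group precondition).
    """
    if len(dispensings) and (
        dispensings["patient_id"].nunique() > 1 or dispensings["drug"].nunique() > 1
    ):
        raise DataError("build_episodes expects one patient and one drug")
    return build_episodes_table(dispensings, config)


def flag_high_dose(episode, config: EpisodeConfig | None = None) -> bool:
    """True when the episode's average daily dose strictly exceeds the
    maximum recommended dose for its drug (an average of exactly the maximum
    is not high-dose)."""
    config = config or EpisodeConfig()
    return bool(
        episode["avg_daily_dose_mg"] > config.max_recommended_mg[episode["drug"]]
    )


def exposure_summary(
    episodes: pd.DataFrame, dispensings: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-patient exposure summary.

    Returns one row per patient with ``n_episodes``, ``median_duration_days``,
    ``any_high_dose``, ``first_high_dose_midpoint`` (NaT when no high-dose
    episode — the first-occurrence midpoint is the event date downstream) and,
    when a dispensing table is supplied, ``n_prescribers`` (distinct
    prescriber ids across the patient's dispensings of this drug).
    """
    if len(episodes) == 0:
        cols = [
            "patient_id",
            "drug",
            "n_episodes",
            "median_duration_days",
            "any_high_dose",
            "first_high_dose_midpoint",
        ]
        return pd.DataFrame(columns=cols)
    eps = episodes.sort_values(["patient_id", "drug", "start_date"], kind="mergesort")
    hd = eps.loc[eps["high_dose"]]
    first_hd = hd.groupby(["patient_id", "drug"])["midpoint_date"].first()
    out = eps.groupby(["patient_id", "drug"]).agg(
        n_episodes=("start_date", "size"),
        median_duration_days=("duration_days", "median"),
        any_high_dose=("high_dose", "any"),
    )
    out["first_high_dose_midpoint"] = first_hd
    out = out.reset_index()
    if dispensings is not None and "prescriber_id" in dispensings.columns:
        n_presc = (
            dispensings.dropna(subset=["prescriber_id"])
            .groupby(["patient_id", "drug"])["prescriber_id"]
            .nunique()
            .rename("n_prescribers")
        )
        out = out.merge(n_presc, on=["patient_id", "drug"], how="left")
        out["n_prescribers"] = out["n_prescribers"].fillna(0).astype(int)
    return out
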