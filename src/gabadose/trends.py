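"""Monthly initiation series and seasonal-trend decomposition.

Initiation is counted per calendar month of cohort entry and expressed per
100,000 inhabitants against a monthly population table.  The series is
decomposed additively into trend + seasonal + remainder with STL
(seasonal-trend decomposition using loess), period 12.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError


def monthly_initiations(
    entries: pd.DataFrame, population: pd.DataFrame
) -> pd.DataFrame:
    """Monthly new users per 100,000 inhabitants.

    ``population`` has columns ``month`` (YYYY-MM) and ``population``.
    Months covered by the population table but with no entries get a zero
    count, so the series is contiguous.
    """
    pop = population.copy()
    pop["month"] = pd.PeriodIndex(pop["month"], freq="M")
    if (pop["population"] <= 0).any():
        bad = pop.loc[pop["population"] <= 0, "month"].iloc[0]
        raise DataError(f"zero population in month {bad}")
    pop = pop.set_index("month").sort_index()

    ent = pd.to_datetime(entries["entry_date"]).dt.to_period("M")
    counts = ent.value_counts().sort_index()
    out = pd.DataFrame(
        {
            "month": pop.index.astype(str),
            "new_users": counts.reindex(pop.index, fill_value=0).to_numpy(),
            "population": pop["population"].to_numpy(),
        }
    )
    out["rate_per_100k"] = 1e5 * out["new_users"] / out["population"]
    return out


def stl_trend(
    series: pd.DataFrame,
    period: int = 12,
    seasonal: int = 13,
    robust: bool = True,
) -> pd.DataFrame:
    """Additive STL decomposition of the monthly rate series.

    Returns the input plus ``trend``, ``seasonal`` and ``remainder`` columns;
    the three components sum to ``rate_per_100k`` elementwise (exactly, up to
    floating-point rounding).
    """
    if len(series) < 2 * period:
        raise DataError(
            f"series has {len(series)} months; need at least {2 * period}"
        )
    from statsmodels.tsa.seasonal import STL

    y = pd.Series(
        series["rate_per_100k"].to_numpy(dtype=float),
        index=pd.PeriodIndex(series["month"], freq="M"),
    )
    res = STL(y, period=period, seasonal=seasonal, robust=robust).fit()
    out = series.copy()
    out["trend"] = res.trend.to_numpy()
    out["seasonal"] = res.seasonal.to_numpy()
    out["remainder"] = res.resid.to_numpy()
    return out


def trend_slope(decomposed: pd.DataFrame) -> float:
    """Least-squares slope of the extracted trend component, per month."""
    t = np.arange(len(decomposed), dtype=float)
    return float(np.polyfit(t, decomposed["trend"].to_numpy(dtype=float), 1)[0])
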