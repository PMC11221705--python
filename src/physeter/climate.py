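"""Monthly effort-normalized presence vs. climate indices at 0 and 8-12 month
lags, on deseasoned series, via ordinary least squares."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tsa.seasonal import STL

__all__ = [
    "ClimateFit",
    "monthly_presence",
    "deseason",
    "lagged_glm",
    "DEFAULT_LAGS",
]

DEFAULT_LAGS = (0, 8, 9, 10, 11, 12)
MIN_MONTHS = 24


@dataclass
class ClimateFit:
    index_name: str
    lag: int
    slope: float
    p_value: float
    r2: float

    @property
    def signed_r(self) -> float:
        """sqrt(R2) carrying the sign of the fitted slope."""
        return float(np.sign(self.slope) * np.sqrt(self.r2))


def monthly_presence(
    hourly: pd.DataFrame,
    presence_col: str = "presence",
    effort_col: str = "effort_min",
    min_effort_min: int = 30,
) -> pd.Series:
    """Mean hourly binary presence per calendar month over effort-valid hours.

    Hours with effort below ``min_effort_min`` are excluded; months with no
    valid hours are NaN.
    """
    if presence_col not in hourly or effort_col not in hourly:
        raise ValueError(f"hourly frame needs columns {presence_col!r}, {effort_col!r}")
    valid = hourly[hourly[effort_col] >= min_effort_min]
    months = pd.PeriodIndex(pd.DatetimeIndex(valid.index), freq="M")
    rate = valid[presence_col].groupby(months).mean()
    all_months = pd.period_range(
        pd.Timestamp(hourly.index.min()), pd.Timestamp(hourly.index.max()), freq="M"
    )
    return rate.reindex(all_months).rename("presence_rate")


def deseason(series: pd.Series, period: int = 12) -> pd.Series:
    """Remove the periodic seasonal component by STL.

    Gaps are linearly interpolated for the decomposition only and re-masked
    afterwards.  Requires at least ``2 * period`` observed months.
    """
    s = pd.Series(series).astype(float)
    mask = s.notna()
    if mask.sum() < 2 * period:
        raise ValueError(f"need >= {2 * period} observed months to deseason")
    filled = s.interpolate(limit_direction="both")
    # a wide seasonal window approximates a strictly periodic component
    res = STL(filled.to_numpy(), period=period, seasonal=121, robust=False).fit()
    out = s - res.seasonal
    out[~mask] = np.nan
    return out.rename(getattr(series, "name", None))


def lagged_glm(
    presence: pd.Series,
    index: pd.Series,
    index_name: str = "index",
    lags: tuple[int, ...] = DEFAULT_LAGS,
    min_overlap: int = MIN_MONTHS,
) -> list[ClimateFit]:
    """OLS of (deseasoned) monthly presence on the climate index at each lag.

    The index is shifted forward by ``lag`` months (presence at month t
    regressed on index at t - lag).  Lags leaving fewer than ``min_overlap``
    paired months are skipped with a warning.
    """
    presence = pd.Series(presence).astype(float)
    index = pd.Series(index).astype(float)
    fits: list[ClimateFit] = []
    for lag in lags:
        shifted = index.shift(lag)
        pair = pd.concat([presence, shifted], axis=1, keys=["y", "x"]).dropna()
        if len(pair) < min_overlap:
            warnings.warn(
                f"lag {lag}: only {len(pair)} overlapping months "
                f"(< {min_overlap}); skipped",
                stacklevel=2,
            )
            continue
        X = sm.add_constant(pair["x"].to_numpy())
        res = sm.OLS(pair["y"].to_numpy(), X).fit()
        fits.append(
            ClimateFit(
                index_name=index_name,
                lag=lag,
                slope=float(res.params[1]),
                p_value=float(res.pvalues[1]),
                r2=float(res.rsquared),
            )
        )
    return fits


def fits_to_frame(fits: list[ClimateFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"index": f.index_name, "lag": f.lag, "slope": f.slope,
             "p": f.p_value, "r2": f.r2, "signed_r": f.signed_r}
            for f in fits
        ],
        columns=["index", "lag", "slope", "p", "r2", "signed_r"],
    )
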