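"""Effort-aware aggregation of classified 5-minute bins into hourly, daily
and weekly presence, class co-occurrence ratios, and deployment-day
accounting."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd

__all__ = [
    "Deployment",
    "deployment_days",
    "site_total",
    "effort_minutes",
    "hourly_presence",
    "weekly_mean_daily_presence",
    "overlap_ratios",
    "unclassified_fraction",
    "MIN_EFFORT_MIN_PER_HOUR",
]

CLASSES = ("SG", "MS", "AM")
ALL_CLASSES = CLASSES + ("UNC",)

#: An hour enters the modeling series only with at least this much recording.
MIN_EFFORT_MIN_PER_HOUR = 30


# ---------------------------------------------------------------------------
# deployments
# ---------------------------------------------------------------------------


@dataclass
class Deployment:
    site: str
    start_date: date
    end_date: date
    duty_cycle: tuple[int, int] | None = None  # (record_min, interval_min)

    def __post_init__(self):
        if isinstance(self.start_date, str):
            self.start_date = _parse_date(self.start_date)
        if isinstance(self.end_date, str):
            self.end_date = _parse_date(self.end_date)
        if self.end_date < self.start_date:
            raise ValueError("end_date must not precede start_date")
        if self.duty_cycle is not None:
            rec, itv = self.duty_cycle
            if not 0 < rec <= itv:
                raise ValueError("duty cycle needs 0 < record_min <= interval_min")


def _parse_date(s: str) -> date:
    for fmt in ("%m/%d/%y", "%m/%d/%Y", "%Y-%m-%d"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unrecognized date {s!r}")


def deployment_days(deployment: Deployment) -> int:
    """Calendar-date difference end - start, in days."""
    return (deployment.end_date - deployment.start_date).days


def site_total(deployments: list[Deployment]) -> int:
    return sum(deployment_days(d) for d in deployments)


# ---------------------------------------------------------------------------
# effort
# ---------------------------------------------------------------------------


def effort_minutes(
    start: pd.Timestamp,
    end: pd.Timestamp,
    freq: str = "h",
    duty_cycle: tuple[int, int] | None = None,
    ship_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
) -> pd.Series:
    """Recording-effort minutes per period over [start, end).

    Effort is exact to the minute: the duty-cycle on/off pattern (anchored at
    ``start``) is applied first, then ship-passage intervals are removed.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    minutes = pd.date_range(start, end, freq="min", inclusive="left")
    on = np.ones(len(minutes), dtype=bool)
    if duty_cycle is not None:
        rec, itv = duty_cycle
        on &= (np.arange(len(minutes)) % itv) < rec
    if ship_intervals:
        for s, e in ship_intervals:
            on &= ~((minutes >= pd.Timestamp(s)) & (minutes < pd.Timestamp(e)))
    per = pd.Series(on.astype(int), index=minutes)
    return per.resample(freq).sum().rename("effort_min")


# ---------------------------------------------------------------------------
# presence aggregation
# ---------------------------------------------------------------------------


def _require_bins(bins: pd.DataFrame) -> pd.DataFrame:
    need = {"bin_start", "n_clicks", "label"}
    if not need.issubset(bins.columns):
        raise ValueError(f"bins frame must have columns {sorted(need)}")
    out = bins.copy()
    out["bin_start"] = pd.DatetimeIndex(out["bin_start"])
    return out


def hourly_presence(
    bins: pd.DataFrame,
    effort_min: pd.Series | None = None,
    min_effort_min: int = MIN_EFFORT_MIN_PER_HOUR,
) -> pd.DataFrame:
    """Hourly per-class binary presence with effort.

    A class is present in an hour iff at least one of its 5-minute bins falls
    in that hour.  Hours with effort below ``min_effort_min`` minutes are
    excluded.  With no effort series, full 60-minute effort is assumed over
    the span of the input bins.
    """
    bins = _require_bins(bins)
    hours_of = bins["bin_start"].dt.floor("h")
    if effort_min is not None:
        hours = pd.DatetimeIndex(effort_min.index)
        eff = effort_min.reindex(hours).fillna(0)
    else:
        if bins.empty:
            return pd.DataFrame(
                columns=["effort_min", *ALL_CLASSES, "ANY"],
                index=pd.DatetimeIndex([], name="hour_start"),
            )
        hours = pd.date_range(hours_of.min(), hours_of.max(), freq="h")
        eff = pd.Series(60, index=hours)

    out = pd.DataFrame({"effort_min": eff}, index=pd.Index(hours, name="hour_start"))
    detected = bins["n_clicks"] > 0
    for cls in ALL_CLASSES:
        sel = bins.loc[(bins["label"] == cls) & detected, "bin_start"].dt.floor("h")
        out[cls] = out.index.isin(set(sel)).astype(int)
    any_sel = bins.loc[detected, "bin_start"].dt.floor("h")
    out["ANY"] = out.index.isin(set(any_sel)).astype(int)
    return out[out["effort_min"] >= min_effort_min]


def weekly_mean_daily_presence(
    bins: pd.DataFrame,
    daily_effort_min: pd.Series | None = None,
    bin_minutes: int = 5,
) -> pd.DataFrame:
    """Mean daily presence minutes per ISO week, per class.

    Daily minutes = ``bin_minutes`` x (count of that class's bins that day);
    the weekly value averages over days of that ISO week having at least one
    effort minute.  Weeks with zero effort are NaN.
    """
    bins = _require_bins(bins)
    days_idx = None
    if daily_effort_min is not None:
        days_idx = pd.DatetimeIndex(daily_effort_min.index).normalize()
        eff = pd.Series(daily_effort_min.values, index=days_idx)
    elif not bins.empty:
        days_idx = pd.date_range(
            bins["bin_start"].min().normalize(),
            bins["bin_start"].max().normalize(),
            freq="D",
        )
        eff = pd.Series(1440, index=days_idx)
    else:
        return pd.DataFrame(columns=list(ALL_CLASSES))

    day_of = bins["bin_start"].dt.normalize()
    daily = pd.DataFrame(index=days_idx)
    for cls in ALL_CLASSES:
        cnt = day_of[(bins["label"] == cls) & (bins["n_clicks"] > 0)].value_counts()
        daily[cls] = cnt.reindex(days_idx).fillna(0) * bin_minutes
    daily["has_effort"] = eff.reindex(days_idx).fillna(0) > 0

    iso = daily.index.isocalendar()
    daily["iso_week"] = list(zip(iso["year"], iso["week"]))
    grouped = daily[daily["has_effort"]].groupby("iso_week")[list(ALL_CLASSES)].mean()
    all_weeks = daily.groupby("iso_week").size().index
    return grouped.reindex(all_weeks)


def overlap_ratios(bins: pd.DataFrame, scale: str = "hourly") -> dict[str, float]:
    """Fraction of presence units in each exclusive class-combination region.

    Units are hours or days; the seven regions (SG, MS, AM alone, the three
    pairs, and the triple) are exclusive and normalized by the number of
    units in which any of the three classes is present, so they sum to 1.
    """
    if scale not in ("hourly", "daily"):
        raise ValueError("scale must be 'hourly' or 'daily'")
    bins = _require_bins(bins)
    unit = bins["bin_start"].dt.floor("h" if scale == "hourly" else "D")
    present: dict[pd.Timestamp, set[str]] = {}
    for cls in CLASSES:
        for u in unit[(bins["label"] == cls) & (bins["n_clicks"] > 0)]:
            present.setdefault(u, set()).add(cls)
    regions = ["SG", "MS", "AM", "SG+MS", "SG+AM", "MS+AM", "SG+MS+AM"]
    counts = dict.fromkeys(regions, 0)
    for classes in present.values():
        key = "+".join(c for c in CLASSES if c in classes)
        counts[key] += 1
    total = len(present)
    out = {k: (v / total if total else 0.0) for k, v in counts.items()}
    out["n_units"] = total
    return out


def unclassified_fraction(bins: pd.DataFrame) -> float:
    """Percentage of detection-bearing 5-minute bins labelled unclassified."""
    bins = _require_bins(bins)
    with_det = bins[bins["n_clicks"] > 0]
    if with_det.empty:
        return 0.0
    return 100.0 * float((with_det["label"] == "UNC").mean())
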