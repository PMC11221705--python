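"""Size/sex classification from modal inter-click intervals and body-length
estimation from inter-pulse intervals.

Classes follow the modal-ICI convention: <= 600 ms social groups (females and
young), >= 800 ms adult males, strictly between the two mid-size animals.
Lengths come from two published photogrammetric regressions switched at 11 m
(the small-animal equation is evaluated first; if it predicts >= 11 m the
large-animal equation is used instead).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SizeClass",
    "FiveMinBin",
    "IpiEstimate",
    "build_icigram",
    "classify_bin",
    "classify_bins",
    "extract_ipi",
    "dedupe_ipis",
    "ipi_to_length",
    "piecewise_audit",
    "class_length_summary",
]

ICI_CELL_MS = 10.0
ICI_MAX_MS = 2000.0
SG_MAX_MS = 600.0
AM_MIN_MS = 800.0

#: Small-animal regression (Gordon 1991): length = a + b*IPI + c*IPI^2.
SMALL_ANIMAL_COEFS = (4.833, 1.453, -0.001)
#: Large-animal regression (Growcott et al. 2011): length = a + b*IPI.
LARGE_ANIMAL_COEFS = (5.796, 1.332)
#: Predicted length at which the large-animal regression takes over.
LENGTH_SWITCH_M = 11.0

IPI_MIN_MS = 2.0
IPI_MAX_MS = 9.0


class SizeClass(str, enum.Enum):
    SOCIAL_GROUP = "SG"
    MID_SIZE = "MS"
    ADULT_MALE = "AM"
    UNCLASSIFIED = "UNC"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass
class FiveMinBin:
    bin_start: pd.Timestamp
    n_clicks: int
    ici_hist: np.ndarray  # counts in 10-ms cells over (0, 2000] ms
    modal_ici_ms: float | None
    label: SizeClass = SizeClass.UNCLASSIFIED
    effort: bool = True


@dataclass
class IpiEstimate:
    time: pd.Timestamp | float
    ipi_ms: float
    length_m: float
    equation: str  # "small_animal" | "large_animal"

    @property
    def unique_key(self) -> float:
        return _round_sig(self.ipi_ms, 4)


# ---------------------------------------------------------------------------
# ICIgram
# ---------------------------------------------------------------------------


def _bin_floor(ts: pd.Timestamp, bin_minutes: int = 5) -> pd.Timestamp:
    return ts.floor(f"{bin_minutes}min")


def build_icigram(
    detection_times: pd.Series | pd.DatetimeIndex,
    effort_mask: pd.Series | None = None,
    bin_minutes: int = 5,
    cell_ms: float = ICI_CELL_MS,
    max_ici_ms: float = ICI_MAX_MS,
) -> list[FiveMinBin]:
    """Histogram successive detection gaps per 5-minute bin.

    ICIs are the successive gaps between detections falling in the same bin,
    collected into ``cell_ms`` cells over (0, ``max_ici_ms``].  ``effort_mask``
    maps bin-start timestamps to a boolean (True = recording); bins absent
    from the mask inherit True.  The returned bins cover the 5-minute grid
    from the first to the last detection (or mask entry) inclusive.
    """
    times = pd.DatetimeIndex(detection_times).sort_values()
    edges = np.arange(0.0, max_ici_ms + cell_ms, cell_ms)

    starts: set[pd.Timestamp] = set()
    if len(times):
        grid0 = _bin_floor(times[0], bin_minutes)
        grid1 = _bin_floor(times[-1], bin_minutes)
        starts.update(pd.date_range(grid0, grid1, freq=f"{bin_minutes}min"))
    if effort_mask is not None:
        starts.update(pd.DatetimeIndex(effort_mask.index))
    if not starts:
        return []

    by_bin = pd.Series(1, index=times).groupby(_bin_floor_index(times, bin_minutes))
    groups = {k: g.index for k, g in by_bin}

    bins: list[FiveMinBin] = []
    for start in sorted(starts):
        in_bin = groups.get(start, pd.DatetimeIndex([]))
        n = len(in_bin)
        if n >= 2:
            icis = np.diff(in_bin.asi8) / 1e6  # ns -> ms
            icis = icis[(icis > 0) & (icis <= max_ici_ms)]
            hist, _ = np.histogram(icis, bins=edges)
        else:
            hist = np.zeros(len(edges) - 1, dtype=int)
        modal = None
        if hist.sum() > 0:
            cell = int(np.argmax(hist))  # argmax ties break toward smaller ICI
            modal = float(edges[cell] + cell_ms / 2)
        effort = True
        if effort_mask is not None and start in effort_mask.index:
            effort = bool(effort_mask.loc[start])
        bins.append(FiveMinBin(start, n, hist, modal, SizeClass.UNCLASSIFIED, effort))
    return bins


def _bin_floor_index(times: pd.DatetimeIndex, bin_minutes: int) -> pd.DatetimeIndex:
    return times.floor(f"{bin_minutes}min")


def classify_bin(
    modal_ici_ms: float | None,
    n_clicks: int,
    has_adjacent_detections: bool,
    min_clicks: int = 10,
) -> SizeClass:
    """Classify one 5-minute bin from its modal ICI.

    A bin is eligible only with at least ``min_clicks`` clicks and at least
    one adjacent bin containing detections.  Boundary rule: modal <= 600 ms
    is SOCIAL_GROUP, modal >= 800 ms is ADULT_MALE, strictly between is
    MID_SIZE.
    """
    if modal_ici_ms is None or n_clicks < min_clicks or not has_adjacent_detections:
        return SizeClass.UNCLASSIFIED
    if modal_ici_ms <= SG_MAX_MS:
        return SizeClass.SOCIAL_GROUP
    if modal_ici_ms >= AM_MIN_MS:
        return SizeClass.ADULT_MALE
    return SizeClass.MID_SIZE


def classify_bins(
    bins: list[FiveMinBin], min_clicks: int = 10, bin_minutes: int = 5
) -> list[FiveMinBin]:
    """Apply :func:`classify_bin` in place over a bin sequence, deriving the
    adjacency flag from the neighbouring grid bins' click counts."""
    counts = {b.bin_start: b.n_clicks for b in bins}
    step = pd.Timedelta(minutes=bin_minutes)
    for b in bins:
        adjacent = counts.get(b.bin_start - step, 0) > 0 or counts.get(
            b.bin_start + step, 0
        ) > 0
        b.label = classify_bin(b.modal_ici_ms, b.n_clicks, adjacent, min_clicks)
    return bins


def bins_to_frame(bins: list[FiveMinBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_start": [b.bin_start for b in bins],
            "n_clicks": [b.n_clicks for b in bins],
            "modal_ici_ms": [b.modal_ici_ms for b in bins],
            "label": [str(b.label) for b in bins],
            "effort": [b.effort for b in bins],
        }
    )


# ---------------------------------------------------------------------------
# IPI extraction and length estimation
# ---------------------------------------------------------------------------


def extract_ipi(
    snippet: np.ndarray,
    fs_hz: float,
    lo_ms: float = IPI_MIN_MS,
    hi_ms: float = IPI_MAX_MS,
    prominence: float = 0.3,
    edge_tol_ms: float = 0.05,
) -> float | None:
    """Inter-pulse interval from the normalized envelope autocorrelation.

    Returns the lag (ms) of the dominant secondary peak within
    [lo_ms, hi_ms] (with ``edge_tol_ms`` slack at the edges), provided its
    normalized height reaches ``prominence``; None otherwise.  Sub-sample
    precision via parabolic interpolation.
    """
    x = np.asarray(snippet, dtype=float)
    if x.size < 8:
        return None
    env = np.abs(signal.hilbert(x))
    ac = signal.correlate(env, env, mode="full")[env.size - 1 :]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]

    pad = 0.5  # ms of search slack so edge peaks are found
    lo_i = max(int(np.floor((lo_ms - pad) * 1e-3 * fs_hz)), 1)
    hi_i = min(int(np.ceil((hi_ms + pad) * 1e-3 * fs_hz)), ac.size - 2)
    if hi_i <= lo_i:
        return None
    win = ac[lo_i : hi_i + 1]
    peaks, _ = signal.find_peaks(win)
    if peaks.size == 0:
        return None
    best = peaks[np.argmax(win[peaks])]
    if win[best] < prominence:
        return None
    i = lo_i + best
    # parabolic refinement around the discrete peak
    y0, y1, y2 = ac[i - 1], ac[i], ac[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    lag_ms = (i + float(np.clip(delta, -1, 1))) / fs_hz * 1e3
    if lag_ms < lo_ms - edge_tol_ms or lag_ms > hi_ms + edge_tol_ms:
        return None
    return float(lag_ms)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def dedupe_ipis(ipis_ms: list[float], sig: int = 4) -> list[float]:
    """Keep the first occurrence per distinct ``sig``-significant-figure value."""
    seen: set[float] = set()
    out: list[float] = []
    for v in ipis_ms:
        key = _round_sig(float(v), sig)
        if key not in seen:
            seen.add(key)
            out.append(float(v))
    return out


def ipi_to_length(
    ipi_ms: float,
    small_coefs: tuple[float, float, float] = SMALL_ANIMAL_COEFS,
    large_coefs: tuple[float, float] = LARGE_ANIMAL_COEFS,
    switch_m: float = LENGTH_SWITCH_M,
    ipi_range_ms: tuple[float, float] = (IPI_MIN_MS, IPI_MAX_MS),
) -> tuple[float, str]:
    """Piecewise IPI-to-body-length regression.

    The small-animal quadratic is evaluated first; if it predicts at least
    ``switch_m`` metres the linear large-animal regression is returned
    instead.  IPIs outside ``ipi_range_ms`` are rejected.
    """
    if not np.isfinite(ipi_ms):
        raise ValueError("ipi_ms must be finite")
    lo, hi = ipi_range_ms
    if not lo <= ipi_ms <= hi:
        raise ValueError(
            f"IPI {ipi_ms} ms outside accepted range [{lo}, {hi}] ms; "
            "no calibrated regression applies"
        )
    a, b, c = small_coefs
    small = a + b * ipi_ms + c * ipi_ms**2
    if small < switch_m:
        return float(small), "small_animal"
    a2, b2 = large_coefs
    return float(a2 + b2 * ipi_ms), "large_animal"


def piecewise_audit(
    ipi_ms_values: np.ndarray,
    small_coefs: tuple[float, float, float] = SMALL_ANIMAL_COEFS,
    large_coefs: tuple[float, float] = LARGE_ANIMAL_COEFS,
    switch_m: float = LENGTH_SWITCH_M,
) -> pd.DataFrame:
    """Report IPIs where the two regressions disagree about the 11-m side.

    For each IPI: the two predictions, which branch the switching rule used,
    and a ``disagree`` flag when the chosen equation's own prediction falls on
    the other side of the switch from the small-animal screen.
    """
    rows = []
    a, b, c = small_coefs
    a2, b2 = large_coefs
    for ipi in np.atleast_1d(ipi_ms_values).astype(float):
        small = a + b * ipi + c * ipi**2
        large = a2 + b2 * ipi
        branch = "small_animal" if small < switch_m else "large_animal"
        chosen = small if branch == "small_animal" else large
        disagree = (chosen >= switch_m) != (small >= switch_m)
        rows.append(
            {
                "ipi_ms": ipi,
                "small_pred_m": small,
                "large_pred_m": large,
                "branch": branch,
                "length_m": chosen,
                "disagree": disagree,
            }
        )
    return pd.DataFrame(rows)


def class_length_summary(
    lengths_m: np.ndarray | list[float],
    labels: list[SizeClass | str],
    sg_misclass_over_m: float = 12.0,
    am_misclass_under_m: float = 10.0,
) -> pd.DataFrame:
    """Per-class length summary: n, median, Q1/Q3 and IQR (linear-interpolated
    quartiles), plus likely-misclassification fractions (social-group animals
    above 12 m, adult males below 10 m)."""
    df = pd.DataFrame(
        {"length_m": np.asarray(lengths_m, dtype=float), "label": [str(l) for l in labels]}
    )
    rows = []
    for cls in SizeClass:
        sub = df.loc[df["label"] == cls.value, "length_m"]
        if sub.empty:
            rows.append(
                {"label": cls.value, "n": 0, "median_m": np.nan, "q1_m": np.nan,
                 "q3_m": np.nan, "iqr_m": np.nan, "misclass_frac": np.nan}
            )
            continue
        q1, med, q3 = np.percentile(sub, [25, 50, 75])
        mis = np.nan
        if cls is SizeClass.SOCIAL_GROUP:
            mis = float((sub > sg_misclass_over_m).mean())
        elif cls is SizeClass.ADULT_MALE:
            mis = float((sub < am_misclass_under_m).mean())
        rows.append(
            {"label": cls.value, "n": int(sub.size), "median_m": med, "q1_m": q1,
             "q3_m": q3, "iqr_m": q3 - q1, "misclass_frac": mis}
        )
    return pd.DataFrame(rows)
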