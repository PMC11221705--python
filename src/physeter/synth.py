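"""Synthetic data generation: acoustic scenes, presence series, climate series.

Every generator takes an explicit seed (or :class:`numpy.random.Generator`)
and is bit-reproducible.  Scenes carry a ground-truth annotation table so
that downstream detection and classification can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ClickTrainSpec",
    "ShipEvent",
    "SceneConfig",
    "PresenceSimConfig",
    "ClimateSimConfig",
    "AcousticScene",
    "generate_multipulse_click",
    "render_scene",
    "simulate_presence",
    "simulate_climate_series",
]

#: Gaussian-envelope padding, in envelope standard deviations, placed before
#: the first and after the last pulse of a generated click.
PULSE_PAD_SDS = 8.0

#: Default Gaussian envelope s.d. of a single pulse (ms).
DEFAULT_PULSE_SD_MS = 0.15


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ClickTrainSpec:
    """One regular click train from a single (simulated) animal."""

    class_label: str
    ici_ms: float
    start_s: float
    end_s: float
    ici_jitter_ms: float = 0.0
    ipi_ms: float = 4.0
    n_pulses: int = 3
    rl_dbpp: float = 135.0
    spectral_peak_hz: float = 10_000.0

    def __post_init__(self):
        if not (np.isfinite(self.ici_ms) and self.ici_ms > 0):
            raise ValueError(f"ici_ms must be positive, got {self.ici_ms}")
        if not (0 < self.ipi_ms < 30):
            raise ValueError(f"ipi_ms must lie in (0, 30) ms, got {self.ipi_ms}")
        if int(self.n_pulses) != self.n_pulses or self.n_pulses < 1:
            raise ValueError(f"n_pulses must be an integer >= 1, got {self.n_pulses}")
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.ici_jitter_ms < 0:
            raise ValueError("ici_jitter_ms must be >= 0")


@dataclass
class ShipEvent:
    """A band-limited low-frequency noise passage."""

    start_s: float
    end_s: float
    level_db: float = 110.0
    band_hz: tuple[float, float] = (500.0, 5_000.0)

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("ship event end_s must exceed start_s")


@dataclass
class SceneConfig:
    fs_hz: float = 200_000.0
    duration_s: float = 60.0
    noise_db: float = 60.0  # broadband RMS level, dB re 1 uPa
    trains: list[ClickTrainSpec] = field(default_factory=list)
    confusers: list[ClickTrainSpec] = field(default_factory=list)
    ship_events: list[ShipEvent] = field(default_factory=list)
    transfer_gain_db: float = 0.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        peaks = [t.spectral_peak_hz for t in list(self.trains) + list(self.confusers)]
        if peaks and self.fs_hz <= 2 * max(peaks):
            raise ValueError("fs_hz must exceed twice the highest synthesized frequency")
        for tr in list(self.trains) + list(self.confusers):
            if tr.end_s > self.duration_s:
                raise ValueError(
                    f"train span ends at {tr.end_s} s but scene is {self.duration_s} s"
                )


@dataclass
class PresenceSimConfig:
    """Hourly binary presence with cyclic season, year effects and AR-1 noise."""

    n_years: int = 2
    peak_day: float = 182.0
    amplitude: float = 1.0
    baseline: float = -1.0
    year_effects: tuple[float, ...] | None = None
    ar1_phi: float = 0.0
    ar1_sd: float = 0.0  # stationary s.d. of the latent AR-1 term
    block_len_h: int = 24
    start_year: int = 2011
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.ar1_phi < 1):
            raise ValueError("ar1_phi must lie in [0, 1)")
        if not (1 <= self.peak_day <= 366):
            raise ValueError("peak_day must lie in [1, 366]")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.year_effects is not None and len(self.year_effects) != self.n_years:
            raise ValueError("year_effects must have one entry per year")


@dataclass
class ClimateSimConfig:
    n_months: int = 120
    index_ar1: float = 0.8
    effect_slope: float = 0.0
    lag_months: int = 8
    noise_sd: float = 0.1
    baseline: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lag_months < 0:
            raise ValueError("lag_months must be >= 0")
        if self.n_months < 0:
            raise ValueError("n_months must be >= 0")
        if not (-1 < self.index_ar1 < 1):
            raise ValueError("index_ar1 must lie in (-1, 1)")


# ---------------------------------------------------------------------------
# acoustic scene
# ---------------------------------------------------------------------------


def pulse_lead_samples(fs_hz: float, pulse_sd_ms: float = DEFAULT_PULSE_SD_MS) -> int:
    """Samples between snippet start and the centre of the first pulse."""
    return int(round(PULSE_PAD_SDS * pulse_sd_ms * 1e-3 * fs_hz))


def generate_multipulse_click(
    ipi_ms: float,
    n_pulses: int,
    fs_hz: float = 200_000.0,
    decay_per_pulse_db: float = 6.0,
    spectral_peak_hz: float = 10_000.0,
    pulse_sd_ms: float = DEFAULT_PULSE_SD_MS,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Synthesize a multipulse click as Gaussian-windowed cosine bursts.

    Pulses are spaced ``ipi_ms`` apart (exact on the sample grid), each
    attenuated by ``decay_per_pulse_db`` relative to its predecessor, with a
    carrier at ``spectral_peak_hz``.

    Returns the waveform snippet; the first pulse centre sits at
    :func:`pulse_lead_samples` samples from the start.
    """
    for name, val in [("ipi_ms", ipi_ms), ("fs_hz", fs_hz), ("spectral_peak_hz", spectral_peak_hz),
                      ("pulse_sd_ms", pulse_sd_ms), ("amplitude", amplitude)]:
        if not (np.isfinite(val) and val > 0):
            raise ValueError(f"{name} must be finite and positive, got {val}")
    if int(n_pulses) != n_pulses or n_pulses < 1:
        raise ValueError(f"n_pulses must be an integer >= 1, got {n_pulses}")
    if spectral_peak_hz >= fs_hz / 2:
        raise ValueError("spectral_peak_hz must be below the Nyquist frequency")

    sd_s = pulse_sd_ms * 1e-3
    lead = pulse_lead_samples(fs_hz, pulse_sd_ms)
    n = 2 * lead + int(round((n_pulses - 1) * ipi_ms * 1e-3 * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    wave = np.zeros(n)
    for k in range(int(n_pulses)):
        tc = lead / fs_hz + k * ipi_ms * 1e-3
        gain = 10 ** (-decay_per_pulse_db * k / 20)
        wave += gain * np.exp(-0.5 * ((t - tc) / sd_s) ** 2) * np.cos(
            2 * np.pi * spectral_peak_hz * (t - tc)
        )
    peak = np.abs(wave).max()
    if peak > 0:
        wave *= amplitude / peak
    return wave


@dataclass
class AcousticScene:
    """A rendered waveform plus its ground-truth annotations."""

    waveform: np.ndarray
    fs_hz: float
    clicks: pd.DataFrame  # columns: time_s, class, rl_dbpp, ipi_ms
    ships: pd.DataFrame  # columns: ship_start_s, ship_end_s, level_db
    transfer_gain_db: float = 0.0

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.fs_hz


def _schedule_train(tr: ClickTrainSpec, rng: np.random.Generator) -> np.ndarray:
    times = []
    t = tr.start_s
    while t < tr.end_s:
        times.append(t)
        gap = tr.ici_ms
        if tr.ici_jitter_ms > 0:
            gap += rng.normal(0.0, tr.ici_jitter_ms)
        t += max(gap, 1.0) * 1e-3  # never collapse below 1 ms
    return np.asarray(times)


def render_scene(config: SceneConfig, seed=0) -> AcousticScene:
    """Render a scene: broadband noise + click trains + confusers + ships.

    Click times in the annotation table refer to the centre of the first
    pulse of each click and are exact on the sample grid.  Peak-to-peak
    amplitudes are scaled so that ``20*log10(pp) + transfer_gain_db``
    reaches each train's ``rl_dbpp``.
    """
    rng = _as_rng(seed)
    fs = config.fs_hz
    n = int(round(config.duration_s * fs))
    noise_rms = 10 ** ((config.noise_db - config.transfer_gain_db) / 20)
    wave = rng.normal(0.0, noise_rms, n)

    rows = []
    for tr in list(config.trains) + list(config.confusers):
        template = generate_multipulse_click(
            tr.ipi_ms, tr.n_pulses, fs, spectral_peak_hz=tr.spectral_peak_hz
        )
        pp = template.max() - template.min()
        scale = 10 ** ((tr.rl_dbpp - config.transfer_gain_db) / 20) / pp
        template = template * scale
        lead = pulse_lead_samples(fs)
        for t_click in _schedule_train(tr, rng):
            i_center = int(round(t_click * fs))
            i0 = i_center - lead
            if i0 < 0 or i0 + len(template) > n:
                # clip against the scene edge but keep the annotation honest
                lo = max(i0, 0)
                hi = min(i0 + len(template), n)
                wave[lo:hi] += template[lo - i0 : hi - i0]
            else:
                wave[i0 : i0 + len(template)] += template
            rows.append(
                {
                    "time_s": i_center / fs,
                    "class": tr.class_label,
                    "rl_dbpp": tr.rl_dbpp,
                    "ipi_ms": tr.ipi_ms,
                }
            )
    clicks = pd.DataFrame(rows, columns=["time_s", "class", "rl_dbpp", "ipi_ms"])
    clicks = clicks.sort_values("time_s", kind="stable").reset_index(drop=True)

    ship_rows = []
    for ev in config.ship_events:
        lo, hi = ev.band_hz
        sos = signal.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
        i0, i1 = int(ev.start_s * fs), min(int(ev.end_s * fs), n)
        raw = rng.normal(0.0, 1.0, i1 - i0)
        band = signal.sosfiltfilt(sos, raw)
        band *= 10 ** ((ev.level_db - config.transfer_gain_db) / 20) / max(
            band.std(), 1e-30
        )
        # taper 0.2 s at the edges to avoid impulsive onsets
        ramp = min(int(0.2 * fs), (i1 - i0) // 2)
        if ramp > 0:
            env = np.ones(i1 - i0)
            env[:ramp] = np.linspace(0, 1, ramp)
            env[-ramp:] = np.linspace(1, 0, ramp)
            band *= env
        wave[i0:i1] += band
        ship_rows.append(
            {"ship_start_s": ev.start_s, "ship_end_s": ev.end_s, "level_db": ev.level_db}
        )
    ships = pd.DataFrame(ship_rows, columns=["ship_start_s", "ship_end_s", "level_db"])

    return AcousticScene(wave, fs, clicks, ships, config.transfer_gain_db)


# ---------------------------------------------------------------------------
# presence simulation
# ---------------------------------------------------------------------------


def _logit(p):
    return math.log(p / (1 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_presence(config: PresenceSimConfig) -> pd.DataFrame:
    """Simulate an hourly binary presence series.

    P(present at hour t) = inv-logit(baseline
                                     + amplitude * cos(2*pi*(day_t - peak_day)/365.25)
                                     + year_effect[year_t] + z_t)

    with z an AR-1 latent series of stationary s.d. ``ar1_sd`` and
    coefficient ``ar1_phi``.  Returns a frame indexed by hour with columns
    ``presence``, ``p``, ``eta``, ``latent``, ``julian_day``, ``year`` and
    ``effort_min`` (constant 60).
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.n_years, month=1, day=1)
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    n = len(hours)

    jday = hours.dayofyear.to_numpy().astype(float)
    season = config.amplitude * np.cos(2 * np.pi * (jday - config.peak_day) / 365.25)

    year_idx = hours.year.to_numpy() - config.start_year
    if config.year_effects is not None:
        year_term = np.asarray(config.year_effects)[year_idx]
    else:
        year_term = np.zeros(n)

    if config.ar1_sd > 0:
        innov_sd = config.ar1_sd * math.sqrt(1 - config.ar1_phi**2)
        eps = rng.normal(0.0, innov_sd, n)
        z = np.empty(n)
        z[0] = rng.normal(0.0, config.ar1_sd)
        for t in range(1, n):
            z[t] = config.ar1_phi * z[t - 1] + eps[t]
    else:
        z = np.zeros(n)

    eta = config.baseline + season + year_term + z
    p = _inv_logit(eta)
    y = (rng.uniform(size=n) < p).astype(int)

    return pd.DataFrame(
        {
            "presence": y,
            "p": p,
            "eta": eta,
            "latent": z,
            "julian_day": jday,
            "year": hours.year,
            "effort_min": 60,
        },
        index=pd.Index(hours, name="hour_start"),
    )


# ---------------------------------------------------------------------------
# climate simulation
# ---------------------------------------------------------------------------


def simulate_climate_series(config: ClimateSimConfig) -> tuple[pd.Series, pd.Series]:
    """Simulate a standardized AR-1 climate index and a lag-coupled presence rate.

    presence[m] = baseline + effect_slope * index[m - lag_months] + noise.

    The index is simulated with ``lag_months`` months of burn-in so the
    presence series is fully defined over its span.  Both series share a
    monthly :class:`~pandas.PeriodIndex`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_months
    idx = pd.period_range("2010-01", periods=n, freq="M")
    if n == 0:
        empty = pd.Series(np.array([]), index=idx, dtype=float)
        return empty, empty.copy()

    phi = config.index_ar1
    total = n + config.lag_months
    innov = rng.normal(0.0, 1.0, total)
    x = np.empty(total)
    x[0] = innov[0] / math.sqrt(1 - phi**2) if phi != 0 else innov[0]
    for t in range(1, total):
        x[t] = phi * x[t - 1] + innov[t]
    x /= x.std() if x.std() > 0 else 1.0  # standardized index

    lagged = x[: total - config.lag_months] if config.lag_months else x
    presence = (
        config.baseline
        + config.effect_slope * lagged[-n:]
        + rng.normal(0.0, config.noise_sd, n)
    )
    index_series = pd.Series(x[-n:], index=idx, name="index")
    presence_series = pd.Series(presence, index=idx, name="presence_rate")
    return index_series, presence_series
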