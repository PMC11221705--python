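"""End-to-end pipeline: simulate (or load) audio, detect, classify, bin,
model, climate-regress, and write a reproducible artifact directory."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, climate, demographics, detect, io_utils, models, synth

__all__ = ["PipelineError", "run_pipeline", "scene_from_config"]

SCENE_KEYS = {"fs_hz", "duration_s", "noise_db", "trains", "confusers", "ship_events",
              "transfer_gain_db"}
TRAIN_KEYS = {"class_label", "ici_ms", "start_s", "end_s", "ici_jitter_ms", "ipi_ms",
              "n_pulses", "rl_dbpp", "spectral_peak_hz"}
SHIP_KEYS = {"start_s", "end_s", "level_db", "band_hz"}
DETECTOR_KEYS = {"lo_hz", "hi_hz", "threshold_dbpp", "lockout_ms", "threshold_k",
                 "peak_cut_hz", "ratio_min"}
CLASSIFIER_KEYS = {"min_clicks", "ipi_prominence"}
PRESENCE_KEYS = {"n_years", "peak_day", "amplitude", "baseline", "year_effects",
                 "ar1_phi", "ar1_sd", "block_len_h", "start_year", "seed"}
CLIMATE_KEYS = {"n_months", "index_ar1", "effect_slope", "lag_months", "noise_sd",
                "baseline", "seed"}
TOP_KEYS = {"scene", "audio", "start_time", "detector", "classifier", "presence_sim",
            "climate_sim", "seed"}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def scene_from_config(cfg: dict) -> synth.SceneConfig:
    io_utils.validate_keys(cfg, SCENE_KEYS, "scene")
    trains = []
    for t in cfg.get("trains", []):
        io_utils.validate_keys(t, TRAIN_KEYS, "scene.trains[]")
        trains.append(synth.ClickTrainSpec(**t))
    confusers = []
    for t in cfg.get("confusers", []):
        io_utils.validate_keys(t, TRAIN_KEYS, "scene.confusers[]")
        confusers.append(synth.ClickTrainSpec(**t))
    ships = []
    for s in cfg.get("ship_events", []):
        io_utils.validate_keys(s, SHIP_KEYS, "scene.ship_events[]")
        if "band_hz" in s:
            s = dict(s, band_hz=tuple(s["band_hz"]))
        ships.append(synth.ShipEvent(**s))
    scalar = {k: v for k, v in cfg.items()
              if k in ("fs_hz", "duration_s", "noise_db", "transfer_gain_db")}
    return synth.SceneConfig(trains=trains, confusers=confusers, ship_events=ships, **scalar)


def run_pipeline(config: dict, outdir, seed: int = 0) -> Path:
    """Run every stage the config enables and write artifacts + manifest.

    Deterministic for a fixed config and seed.  Raises
    :class:`PipelineError` naming the failed stage.
    """
    io_utils.validate_keys(config, TOP_KEYS, "pipeline config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed))
    artifacts: list[Path] = []
    report: list[str] = ["# Pipeline report", ""]

    # -- stage: audio ------------------------------------------------------
    scene = None
    wave = fs = None
    gain = 0.0
    try:
        if "scene" in config:
            scene = scene_from_config(config["scene"])
            rendered = synth.render_scene(scene, seed=seed)
            wave, fs, gain = rendered.waveform, rendered.fs_hz, rendered.transfer_gain_db
            artifacts.append(io_utils.write_csv(rendered.clicks, outdir / "truth_clicks.csv",
                                                "truth-clicks"))
            artifacts.append(io_utils.write_csv(rendered.ships, outdir / "truth_ships.csv",
                                                "truth-ships"))
            report.append(f"Simulated scene: {rendered.duration_s:.1f} s at {fs:.0f} Hz, "
                          f"{len(rendered.clicks)} scheduled clicks.")
        elif "audio" in config:
            fs, wave = io_utils.read_wav(config["audio"])
            report.append(f"Loaded audio: {len(wave) / fs:.1f} s at {fs:.0f} Hz.")
        else:
            raise ValueError("config needs a 'scene' or 'audio' entry")
    except (OSError, ValueError) as exc:
        raise PipelineError("audio", str(exc)) from exc

    # -- stage: detect -----------------------------------------------------
    try:
        dcfg = dict(config.get("detector", {}))
        io_utils.validate_keys(dcfg, DETECTOR_KEYS, "detector")
        filtered = detect.bandpass(wave, fs, dcfg.get("lo_hz", 5_000.0),
                                   dcfg.get("hi_hz", 95_000.0))
        dets = detect.detect_clicks(
            filtered, fs,
            lockout_ms=dcfg.get("lockout_ms", 30.0),
            threshold_k=dcfg.get("threshold_k", 8.0),
            transfer_gain_db=gain,
        )
        dets = detect.rl_filter(dets, dcfg.get("threshold_dbpp", 125.0))
        labels = [
            detect.spectral_shape_classify(
                d, dcfg.get("peak_cut_hz", 20_000.0), dcfg.get("ratio_min", 1.0))
            if d.psd_db is not None else "other"
            for d in dets
        ]
        frame = detect.detections_to_frame(dets)
        frame["label"] = labels
        artifacts.append(io_utils.write_csv(frame, outdir / "detections.csv", "detections"))
        accepted = [d for d, lab in zip(dets, labels) if lab == "sperm_whale"]
        report.append(f"Detections: {len(dets)} above threshold, "
                      f"{len(accepted)} classified as sperm whale.")
    except ValueError as exc:
        raise PipelineError("detect", str(exc)) from exc

    # -- stage: classify ---------------------------------------------------
    try:
        start_time = pd.Timestamp(config.get("start_time", "2017-06-01T00:00:00"))
        acc_frame = frame[frame["label"] == "sperm_whale"]
        times = start_time + pd.to_timedelta(acc_frame["time_s"], unit="s")
        bins = demographics.build_icigram(times)
        demographics.classify_bins(bins, config.get("classifier", {}).get("min_clicks", 10))
        bins_df = demographics.bins_to_frame(bins)
        artifacts.append(io_utils.write_csv(bins_df, outdir / "bins.csv", "bins"))

        ipis, ipi_rows = [], []
        for d in accepted:
            ipi = demographics.extract_ipi(d.snippet, d.fs_hz)
            if ipi is not None:
                ipis.append((d.time_s, ipi))
        for t, ipi in zip(
            [t for t, _ in ipis], demographics.dedupe_ipis([i for _, i in ipis])
        ):
            length, eq = demographics.ipi_to_length(ipi)
            ipi_rows.append({"time_s": t, "ipi_ms": ipi, "length_m": length, "equation": eq})
        ipi_df = pd.DataFrame(ipi_rows, columns=["time_s", "ipi_ms", "length_m", "equation"])
        artifacts.append(io_utils.write_csv(ipi_df, outdir / "ipi.csv", "ipi"))
        report.append(f"Classified {len(bins_df)} five-minute bins; "
                      f"{len(ipi_df)} unique IPI length estimates.")
    except ValueError as exc:
        raise PipelineError("classify", str(exc)) from exc

    # -- stage: bin --------------------------------------------------------
    try:
        hourly = binning.hourly_presence(bins_df)
        artifacts.append(io_utils.write_csv(hourly.reset_index(), outdir / "presence.csv",
                                            "presence"))
        overlaps = {scale: binning.overlap_ratios(bins_df, scale)
                    for scale in ("hourly", "daily")}
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(overlaps, fh, indent=2)
        artifacts.append(outdir / "overlap.json")
        report.append(f"Unclassified fraction: "
                      f"{binning.unclassified_fraction(bins_df):.1f}% of detection bins.")
    except ValueError as exc:
        raise PipelineError("bin", str(exc)) from exc

    # -- stage: model (simulated presence) ---------------------------------
    if "presence_sim" in config:
        try:
            pcfg = dict(config["presence_sim"])
            io_utils.validate_keys(pcfg, PRESENCE_KEYS, "presence_sim")
            pcfg.setdefault("seed", seed)
            if "year_effects" in pcfg and pcfg["year_effects"] is not None:
                pcfg["year_effects"] = tuple(pcfg["year_effects"])
            sim = synth.simulate_presence(synth.PresenceSimConfig(**pcfg))
            glm_fit = models.fit_gee(
                sim, models.ModelSpec("presence", ["julian_day"], corstr="independence"))
            block = models.block_size_from_acf(sim["presence"] - glm_fit.fittedvalues)
            spec = models.ModelSpec("presence", ["julian_day"], block_len_h=block)
            trace = models.backward_select(sim, spec)
            final = models.wald_prune(trace.final_fit)
            coef = pd.DataFrame({"term": final.X.columns, "estimate": np.asarray(final.params),
                                 "robust_se": np.sqrt(np.diag(final.cov_robust))})
            artifacts.append(io_utils.write_csv(coef, outdir / "gee_coefficients.csv",
                                                "gee-coefficients"))
            artifacts.append(io_utils.write_csv(final.wald_table(), outdir / "gee_wald.csv",
                                                "gee-wald"))
            if "julian_day" in final.terms:
                pf = final.partial_fit("julian_day", seed=seed)
                artifacts.append(io_utils.write_csv(pf, outdir / "gee_partial_jd.csv",
                                                    "gee-partial"))
            diag = models.diagnostics(final)
            diag["block_len_h"] = block
            with open(outdir / "gee_diagnostics.json", "w") as fh:
                json.dump(diag, fh, indent=2)
            artifacts.append(outdir / "gee_diagnostics.json")
            report.append(f"GEE fit: block {block} h, "
                          f"Tjur R2 {diag['tjur_r2']:.3f}.")
        except (ValueError, RuntimeError) as exc:
            raise PipelineError("model", str(exc)) from exc

    # -- stage: climate (simulated series) ---------------------------------
    if "climate_sim" in config:
        try:
            ccfg = dict(config["climate_sim"])
            io_utils.validate_keys(ccfg, CLIMATE_KEYS, "climate_sim")
            ccfg.setdefault("seed", seed)
            index, rate = synth.simulate_climate_series(synth.ClimateSimConfig(**ccfg))
            des = climate.deseason(rate)
            fits = climate.lagged_glm(des, index, index_name="sim_index")
            artifacts.append(io_utils.write_csv(climate.fits_to_frame(fits),
                                                outdir / "climate_fits.csv", "climate-fits"))
            report.append(f"Climate GLMs: {len(fits)} lags fitted.")
        except (ValueError, RuntimeError) as exc:
            raise PipelineError("climate", str(exc)) from exc

    # -- manifest + report -------------------------------------------------
    manifest = {p.name: io_utils.sha256_of(p) for p in artifacts}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (outdir / "report.md").write_text("\n".join(report) + "\n")
    return outdir
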