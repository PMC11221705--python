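import numpy as np
import pandas as pd
import pytest

from physeter import detect, synth


@pytest.fixture(scope="session")
def small_scene():
    """A 5.5 s scene with one ICI-500 ms train of 10 high-SNR clicks."""
    trains = [
        synth.ClickTrainSpec("AM", ici_ms=500, start_s=0.25, end_s=5.0, rl_dbpp=135.0)
    ]
    cfg = synth.SceneConfig(duration_s=5.5, noise_db=90.0, trains=trains)
    return synth.render_scene(cfg, seed=1)


@pytest.fixture(scope="session")
def small_scene_detections(small_scene):
    filtered = detect.bandpass(small_scene.waveform, small_scene.fs_hz)
    return detect.detect_clicks(filtered, small_scene.fs_hz)


def make_bins_frame(rows):
    """rows: list of (bin_start_iso, n_clicks, label)."""
    return pd.DataFrame(
        {
            "bin_start": pd.DatetimeIndex([r[0] for r in rows]),
            "n_clicks": [r[1] for r in rows],
            "label": [r[2] for r in rows],
        }
    )


@pytest.fixture
def bins_frame_factory():
    return make_bins_frame
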