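import numpy as np
import pytest

from ehgkit import channel_auc_map, process_recording, recording_metrics
from ehgkit.synthetic import make_layout, preset_config, simulate_recording

SUITE_SEED = 12345  # pinned seed for the preset-based suites


def run_preset(preset: str, seed: int, n_channels: int | None = None) -> dict:
    """Simulate one preset recording and run the full processing chain."""
    overrides = {"n_channels": n_channels} if n_channels else {}
    cfg = preset_config(preset, seed, **overrides)
    layout = make_layout(cfg.n_channels, seed=seed)
    rec, truth = simulate_recording(cfg, layout)
    slow, fast, enhanced = process_recording(rec)
    mask = truth.mask(5.0)
    mask.values = mask.values[: fast.n_samples]
    return {
        "layout": layout,
        "truth": truth,
        "slow": slow,
        "fast": fast,
        "enhanced": enhanced,
        "mask": mask,
    }


@pytest.fixture(scope="session")
def low_snr_run() -> dict:
    """Processed low-SNR suite (20 channels, pinned seed) with AUC maps and metrics."""
    out = run_preset("low_snr", SUITE_SEED)
    out["auc_fast"] = channel_auc_map(out["fast"], out["mask"], out["layout"])
    out["auc_enhanced"] = channel_auc_map(out["enhanced"], out["mask"], out["layout"])
    out["metrics_fast"] = recording_metrics(out["fast"])
    out["metrics_enhanced"] = recording_metrics(out["enhanced"])
    return out


@pytest.fixture(scope="session")
def high_snr_run() -> dict:
    """Processed high-SNR suite (20 channels, pinned seed) with AUC maps."""
    out = run_preset("high_snr", SUITE_SEED)
    out["auc_fast"] = channel_auc_map(out["fast"], out["mask"], out["layout"])
    out["auc_enhanced"] = channel_auc_map(out["enhanced"], out["mask"], out["layout"])
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250930)
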