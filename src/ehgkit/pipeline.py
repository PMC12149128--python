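"""End-to-end pipeline: simulate/load -> band-split -> enhance -> evaluate.

A single YAML config drives every stage with the standard defaults
(fourth-order Butterworth, 0.01-0.1 and 0.34-1 Hz bands, 5 Hz working rate,
10 s window, 0.95 trimming quantile, +-3 sigma threshold grid, 0.8 AUC
consistency threshold, alpha = 0.05). Outputs are a pure function of
(inputs, config, seed); a manifest records the config hash and per-stage
log lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import channel_auc_map
from .enhance import enhance_recording
from .io import (
    read_layout,
    read_mask,
    read_recording,
    write_intervals,
    write_layout,
    write_mask,
    write_recording,
)
from .metrics import recording_metrics
from .preprocess import BandSpec, bandpass, resample_to, screen_channels
from .spatial import spatial_comparison
from .stats import compare_bands, comparisons_frame
from .synthetic import make_layout, preset_config, simulate_recording

__all__ = ["PipelineConfig", "run_pipeline", "process_recording"]

OVERSMOOTH_WINDOW_S = 30.0  # contractions last 30-90 s; longer windows oversmooth


@dataclass
class PipelineConfig:
    """Validated parameters for the full pipeline."""

    seed: int = 0
    # input: either a synthetic preset ...
    preset: str | None = "low_snr"
    n_channels: int | None = None
    # ... or recorded data
    recording: str | None = None
    recording_format: str = "delimited"
    mask: str | None = None
    layout: str | None = None
    # processing parameters
    slow_band: tuple[float, float] = (0.01, 0.1)
    fast_band: tuple[float, float] = (0.34, 1.0)
    filter_order: int = 4
    fs_out: float = 5.0
    window_s: float = 10.0
    trim_quantile: float = 0.95
    auc_threshold: float = 0.8
    alpha: float = 0.05
    projected: bool = True

    def __post_init__(self) -> None:
        if self.window_s > OVERSMOOTH_WINDOW_S:
            warnings.warn(
                f"window_s={self.window_s} exceeds {OVERSMOOTH_WINDOW_S} s and "
                "will oversmooth: uterine contractions last 30-90 s",
                stacklevel=2,
            )
        if self.recording is None and self.preset is None:
            raise ValueError("config needs either a synthetic preset or a recording")
        if not 0 < self.trim_quantile < 1:
            raise ValueError("trim_quantile must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("slow_band", "fast_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sha256(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def process_recording(
    raw,
    fs_out: float = 5.0,
    window_s: float = 10.0,
    slow_band: tuple[float, float] = (0.01, 0.1),
    fast_band: tuple[float, float] = (0.34, 1.0),
    order: int = 4,
    screen: bool = False,
):
    """Band-split, downsample and enhance one raw recording.

    Returns ``(slow, fast, enhanced)`` recordings at ``fs_out``. With
    ``screen=True`` low-quality channels are dropped first (fast-wave
    amplitude screen). Convenience wrapper over the stage functions.
    """
    n_win = int(round(window_s * fs_out))
    slow = resample_to(bandpass(raw, BandSpec(*slow_band, order)), fs_out)
    fast = resample_to(bandpass(raw, BandSpec(*fast_band, order)), fs_out)
    if screen:
        kept = screen_channels(fast).kept
        if not kept:
            raise ValueError("no channel passed quality screening")
        slow, fast = slow.select(kept), fast.select(kept)
    return slow, fast, enhance_recording(fast, slow, n_win)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> dict:
    """Run every stage and write CSV results plus a manifest to ``out_dir``.

    Returns the manifest dict. Raises (naming the stage) on the first
    failing stage.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stage = "setup"
    try:
        stage = "input"
        if config.recording is not None:
            raw = read_recording(config.recording, config.recording_format)
            layout = read_layout(config.layout) if config.layout else None
            truth = None
            log.append(f"input: loaded {raw.n_channels}x{raw.n_samples} @ {raw.fs} Hz")
        else:
            overrides = {}
            if config.n_channels is not None:
                overrides["n_channels"] = config.n_channels
            cfg = preset_config(config.preset, config.seed, **overrides)
            layout = make_layout(cfg.n_channels, seed=cfg.seed)
            raw, truth = simulate_recording(cfg, layout)
            write_layout(layout, out / "layout.csv")
            write_intervals(truth.intervals, out / "truth_intervals.csv")
            log.append(
                f"input: simulated preset {config.preset!r}, "
                f"{raw.n_channels} channels, {len(truth.intervals)} contractions"
            )

        stage = "preprocess"
        n_win = int(round(config.window_s * config.fs_out))
        slow = resample_to(
            bandpass(raw, BandSpec(*config.slow_band, config.filter_order)), config.fs_out
        )
        fast = resample_to(
            bandpass(raw, BandSpec(*config.fast_band, config.filter_order)), config.fs_out
        )
        quality = screen_channels(fast)
        _write_csv(quality.table, out / "quality.csv")
        kept = quality.kept
        if not kept:
            raise ValueError("no channel passed quality screening")
        slow, fast = slow.select(kept), fast.select(kept)
        write_recording(slow, out / "slow.csv")
        write_recording(fast, out / "fast.csv")
        log.append(f"preprocess: kept {len(kept)}/{raw.n_channels} channels at {config.fs_out} Hz")

        stage = "enhance"
        enhanced = enhance_recording(fast, slow, n_win)
        write_recording(enhanced, out / "enhanced.csv")
        log.append(f"enhance: window {n_win} samples ({config.window_s} s)")

        stage = "mask"
        if config.mask is not None:
            mask = read_mask(config.mask, config.fs_out, duration_s=raw.duration_s)
        elif truth is not None:
            mask = truth.mask(config.fs_out)
        else:
            raise ValueError("no contraction mask available (provide 'mask')")
        mask.values = mask.values[: fast.n_samples]
        if len(mask.values) < fast.n_samples:
            raise ValueError("mask shorter than the processed recording")
        write_mask(mask, out / "mask.csv")
        log.append(f"mask: {mask.positive_fraction:.1%} positive samples")

        stage = "metrics"
        mf = recording_metrics(fast, n_win, config.trim_quantile)
        me = recording_metrics(enhanced, n_win, config.trim_quantile)
        _write_csv(pd.concat([mf, me], ignore_index=True), out / "metrics.csv")
        log.append("metrics: skewness/kurtosis/PAER per channel per band")

        stage = "detect"
        auc_fast = channel_auc_map(fast, mask, layout, n_win)
        auc_enh = channel_auc_map(enhanced, mask, layout, n_win)
        _write_csv(auc_fast.assign(band="fast"), out / "auc_fast.csv")
        _write_csv(auc_enh.assign(band="enhanced"), out / "auc_enhanced.csv")
        log.append(
            f"detect: median AUC fast={auc_fast['auc'].median():.3f} "
            f"enhanced={auc_enh['auc'].median():.3f}"
        )

        stage = "spatial"
        if layout is not None:
            sp = spatial_comparison(
                auc_fast, auc_enh, layout, config.auc_threshold, config.projected
            )
            _write_csv(sp, out / "spatial.csv")
            log.append("spatial: consistency sets, hulls, growth ratios")
        else:
            sp = None
            log.append("spatial: skipped (no layout)")

        stage = "stats"
        comps = comparisons_frame(compare_bands(mf, me, "pooled"))
        _write_csv(comps, out / "stats.csv")
        log.append("stats: paired Wilcoxon fast vs enhanced")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "ehgkit_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": config.sha256(),
        "config": dataclasses.asdict(config),
        "stages": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
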