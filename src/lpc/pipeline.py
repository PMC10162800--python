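"""End-to-end orchestration: recording -> GP -> LPC boundary, CSD, power,
rates, drift — with a provenance block for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .coupling import detect_phase_reversal, lpc_matrix, lpc_over_epochs
from .csd import compute_csd, evoked_average, find_input_layer
from .errors import EstimationError, LPCError
from .io import LaminarRecording
from .power import band_power_profile, firing_rate_profile, power_crossover
from .signal import compute_generalized_phase

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full analysis run."""

    band: tuple = (5.0, 50.0)
    filter_order: int = 4
    min_spikes: int = 300
    min_strength: float = float(np.pi / 2)
    weight_by_spi: bool = True
    window_s: float = 180.0
    step_s: float = 180.0
    csd_window: tuple = (0.05, 0.25)
    threshold_frac: float = 0.5
    low_band: tuple = (8.0, 30.0)
    high_band: tuple = (65.0, 100.0)
    seed: int = 0
    out_dir: str | None = None


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(rec: LaminarRecording, cfg: RunConfig | None = None) -> dict:
    """Run every laminar estimator a recording supports.

    Returns a JSON-serializable report with the LPC boundary estimate, the
    power crossover, the normalized rate profile, the epoch-drift series,
    CSD input-layer bounds when events are present (marked skipped
    otherwise), and a provenance block. Deterministic given the recording
    and config.
    """
    cfg = cfg or RunConfig()
    report: dict = {}
    gp = compute_generalized_phase(rec.lfp, rec.fs_lfp, band=cfg.band,
                                   order=cfg.filter_order)
    matrix = lpc_matrix(rec, gp, min_spikes=cfg.min_spikes)
    try:
        est = detect_phase_reversal(matrix, min_strength=cfg.min_strength,
                                    weight_by_spi=cfg.weight_by_spi)
        report["lpc"] = dataclasses.asdict(est)
    except EstimationError as exc:
        report["lpc"] = {"error": f"lpc: {exc}"}

    if rec.duration_s >= cfg.window_s:
        drift = lpc_over_epochs(rec, gp, window_s=cfg.window_s, step_s=cfg.step_s,
                                min_spikes=cfg.min_spikes,
                                min_strength=cfg.min_strength,
                                weight_by_spi=cfg.weight_by_spi)
        report["drift"] = [
            {"epoch_start_s": t, **dataclasses.asdict(e)} for t, e in drift
        ]
    else:
        report["drift"] = "skipped: record shorter than one epoch window"

    try:
        profile = band_power_profile(rec.lfp, rec.fs_lfp, low=cfg.low_band,
                                     high=cfg.high_band)
        depth, detected = power_crossover(profile, rec.channel_depths_um)
        report["power"] = {
            "low_z": profile.low_z.tolist(),
            "high_z": profile.high_z.tolist(),
            "crossover_depth_um": depth if detected else None,
            "detected": detected,
        }
    except LPCError as exc:
        report["power"] = {"error": f"power: {exc}"}

    rates = firing_rate_profile(rec)
    report["rates"] = {
        "normalized": rates.normalized.tolist(),
        "mean_rate_hz": rates.mean_rate_hz,
        "defined": rates.defined,
    }

    if rec.events is not None and rec.events.size:
        try:
            erp, times = evoked_average(rec.lfp, rec.fs_lfp, rec.events,
                                        window=cfg.csd_window)
            cmap = compute_csd(erp, rec.spacing_um, times=times, smooth=False)
            sink = find_input_layer(cmap, threshold_frac=cfg.threshold_frac)
            report["csd"] = {
                "input_top_channel": sink.input_top,
                "input_bottom_channel": sink.input_bottom,
                "onset_latency_s": None if not sink.detected
                else sink.onset_latency_s,
                "detected": sink.detected,
            }
        except LPCError as exc:
            report["csd"] = {"error": f"csd: {exc}"}
    else:
        report["csd"] = "skipped: no stimulus events"

    report["provenance"] = {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "package_version": __version__,
        "n_channels": rec.n_channels,
        "duration_s": rec.duration_s,
    }
    return report
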