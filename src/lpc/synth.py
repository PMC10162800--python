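"""Synthetic laminar recordings with known ground truth.

The generator emulates the laminar features the analysis targets:

* a shared band-limited (5-50 Hz) drive whose polarity flips at a known
  boundary channel — the electrical-dipole picture of the input/deep
  transition — so the preferred spike-LFP angle is near +-pi against
  superficial/input LFP and near 0 against deep LFP;
* spikes from an inhomogeneous Poisson process whose rate is von Mises
  modulated by the drive's generalized phase, with layer-specific
  concentration (superficial > input > deep) and base rates (superficial
  lower than input/deep);
* 1/f background noise per channel;
* an optional laminar spectral gradient: extra 65-100 Hz noise above the
  boundary and extra 8-30 Hz noise below it, so the high/low power
  crossover sits at the boundary;
* an optional drift schedule re-labelling the flip depth over time, and
  evoked trials with a current sink injected at known channels.

Channel indices are 0-based; ``boundary_channel`` is the deepest channel on
the superficial side of the flip.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import i0

from .errors import ParameterError
from .io import EventTable, LaminarRecording
from .signal import bandpass_forward_reverse, compute_generalized_phase

__all__ = ["SynthConfig", "generate_recording", "generate_evoked_trials"]


@dataclass
class SynthConfig:
    """Ground-truth parameters of a synthetic laminar session.

    Defaults follow a 32-contact probe at 100 um spacing sampled at 1 kHz,
    with coupling concentration decreasing with depth (kappa 0.35 / 0.25 /
    0.15) and base rates 2 / 6 / 5 Hz for superficial / input / deep
    channels. ``noise_sd`` and ``spectral_gradient`` are amplitudes relative
    to the unit-variance shared drive.
    """

    n_channels: int = 32
    spacing_um: float = 100.0
    boundary_channel: int = 15
    duration_s: float = 600.0
    fs_lfp: float = 1000.0
    kappa_sup: float = 0.35
    kappa_in: float = 0.25
    kappa_deep: float = 0.15
    rate_sup: float = 2.0
    rate_in: float = 6.0
    rate_deep: float = 5.0
    band: tuple = (5.0, 50.0)
    noise_sd: float = 0.5
    spectral_gradient: float = 0.5
    input_thickness: int = 5
    transition_width: float = 0.0
    amp_uV: float = 100.0
    drift_schedule: list | None = None
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.boundary_channel < self.n_channels:
            raise ParameterError("boundary_channel must satisfy 1 <= b < n_channels")
        if min(self.kappa_sup, self.kappa_in, self.kappa_deep) < 0:
            raise ParameterError("kappa values must be non-negative")
        if min(self.rate_sup, self.rate_in, self.rate_deep) < 0:
            raise ParameterError("rates must be non-negative")
        if self.duration_s < 1 or self.fs_lfp <= 0:
            raise ParameterError("need duration >= 1 s and positive fs")

    def layer_labels(self, boundary: int | None = None):
        """Per-channel layer labels for a given flip position."""
        b = self.boundary_channel if boundary is None else boundary
        top = max(0, b - self.input_thickness + 1)
        labels = []
        for ch in range(self.n_channels):
            if ch < top:
                labels.append("superficial")
            elif ch <= b:
                labels.append("input")
            else:
                labels.append("deep")
        return labels


def _pink_noise(rng, n, fs):
    """Unit-variance 1/f-amplitude Gaussian noise (flat below 1 Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec = shaping * (rng.standard_normal(freqs.size)
                      + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(rng, n, fs, band):
    x = bandpass_forward_reverse(rng.standard_normal(n), fs, band[0], band[1])
    return x / x.std()


def _sign_profile(cfg: SynthConfig, boundary: int):
    ch = np.arange(cfg.n_channels, dtype=np.float64)
    if cfg.transition_width > 0:
        return np.tanh((boundary + 0.5 - ch) / cfg.transition_width)
    return np.where(ch <= boundary, 1.0, -1.0)


def _layer_params(cfg: SynthConfig, boundary: int):
    kappa = {"superficial": cfg.kappa_sup, "input": cfg.kappa_in,
             "deep": cfg.kappa_deep}
    rate = {"superficial": cfg.rate_sup, "input": cfg.rate_in,
            "deep": cfg.rate_deep}
    labels = cfg.layer_labels(boundary)
    return (np.array([kappa[l] for l in labels]),
            np.array([rate[l] for l in labels]))


def _segments(cfg: SynthConfig):
    """Drift schedule as [(t0, t1, boundary), ...] covering the record."""
    sched = cfg.drift_schedule or [(0.0, cfg.boundary_channel)]
    sched = sorted((float(t), int(b)) for t, b in sched)
    if sched[0][0] > 0:
        sched.insert(0, (0.0, cfg.boundary_channel))
    out = []
    for i, (t, b) in enumerate(sched):
        t1 = sched[i + 1][0] if i + 1 < len(sched) else cfg.duration_s
        if t1 > t:
            out.append((t, t1, b))
    return out


def _von_mises_poisson(rng, phase, fs, t0, t1, rate_hz, kappa, mu=np.pi):
    """Spike times on [t0, t1) with rate r*exp(kappa*cos(phi - mu))/I0(kappa),
    by thinning a homogeneous Poisson process."""
    if rate_hz <= 0:
        return np.empty(0)
    rmax = rate_hz * np.exp(kappa) / i0(kappa)
    n_cand = rng.poisson(rmax * (t1 - t0))
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    idx = np.minimum(np.round(cand * fs).astype(np.int64), phase.size - 1)
    # acceptance ratio rate(t)/rmax = exp(kappa * (cos(phi - mu) - 1))
    accept_p = np.exp(kappa * (np.cos(phase[idx] - mu) - 1.0))
    keep = rng.uniform(size=n_cand) < accept_p
    return cand[keep]


def generate_recording(cfg: SynthConfig):
    """Simulate a laminar session; returns ``(LaminarRecording, truth)``.

    ``truth`` records the boundary channel, per-channel layer labels,
    kappa/rate vectors and the drift schedule actually applied.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_lfp
    n = int(round(cfg.duration_s * fs))
    drive = _band_noise(rng, n, fs, cfg.band)
    gp_drive = compute_generalized_phase(drive[None, :], fs, band=cfg.band)
    phi = gp_drive.phase[0]

    segs = _segments(cfg)
    sign = np.empty((cfg.n_channels, n))
    for t0, t1, b in segs:
        i0_, i1_ = int(round(t0 * fs)), int(round(t1 * fs))
        sign[:, i0_:i1_] = _sign_profile(cfg, b)[:, None]

    lfp = sign * drive[None, :]
    b0 = cfg.boundary_channel
    for ch in range(cfg.n_channels):
        if cfg.noise_sd > 0:
            lfp[ch] += cfg.noise_sd * _pink_noise(rng, n, fs)
        if cfg.spectral_gradient > 0:
            if ch <= b0:
                lfp[ch] += cfg.spectral_gradient * _band_noise(rng, n, fs, (65.0, 100.0))
            else:
                lfp[ch] += cfg.spectral_gradient * _band_noise(rng, n, fs, (8.0, 30.0))
    lfp *= cfg.amp_uV

    spikes = []
    seg_params = [(t0, t1, *_layer_params(cfg, b)) for t0, t1, b in segs]
    for ch in range(cfg.n_channels):
        parts = []
        for t0, t1, kappas, rates in seg_params:
            parts.append(_von_mises_poisson(rng, phi, fs, t0, t1,
                                            rates[ch], kappas[ch]))
        train = np.concatenate(parts) if parts else np.empty(0)
        spikes.append(np.sort(train[train < cfg.duration_s]))

    depths = np.arange(cfg.n_channels) * cfg.spacing_um
    rec = LaminarRecording(
        lfp=lfp,
        fs_lfp=fs,
        channel_depths_um=depths,
        spikes=spikes,
        meta={"generator": "lpc.synth", "config": asdict(cfg)},
    )
    kappas, rates = _layer_params(cfg, b0)
    truth = {
        "boundary_channel": b0,
        "boundary_depth_um": float(depths[b0]),
        "layers": cfg.layer_labels(),
        "kappa": kappas.tolist(),
        "rate_hz": rates.tolist(),
        "segments": segs,
    }
    return rec, truth


def _sink_lfp_profile(n_channels: int, sink: tuple, spacing_um: float):
    """Depth profile whose discrete second difference is a sink (negative
    CSD) exactly on ``sink`` channels and sources on the flanking channels,
    zero elsewhere; the injected second difference sums to zero."""
    top, bottom = sink
    if top > bottom:
        raise ParameterError("sink top must not exceed bottom")
    if top - 1 < 1 or bottom + 1 > n_channels - 2:
        raise ParameterError(
            "sink needs flanking source channels inside the probe interior"
        )
    m = bottom - top + 1
    target_csd = np.zeros(n_channels)
    target_csd[top:bottom + 1] = -1.0
    target_csd[top - 1] = target_csd[bottom + 1] = m / 2.0
    d2 = -target_csd  # compute_csd negates the second difference
    h_mm = spacing_um / 1000.0
    v = np.zeros(n_channels)
    for i in range(1, n_channels - 1):
        v[i + 1] = 2 * v[i] - v[i - 1] + h_mm**2 * d2[i]
    return v / np.abs(v).max(), target_csd


def generate_evoked_trials(cfg: SynthConfig, n_trials: int, sink_channels=(12, 16),
                           onset_s: float = 0.025, noise_sd: float = 0.0,
                           trial_period_s: float = 0.6,
                           event_offset_s: float = 0.15,
                           sigma_s: float = 0.010,
                           noise_spatial_sigma_ch: float = 3.0):
    """Continuous LFP with stimulus-locked sink/source transients.

    Each trial injects the sink depth profile with a Gaussian time course
    (SD ``sigma_s``) whose half-maximum rise sits exactly ``onset_s`` after
    the event, so a half-minimum threshold detector recovers the configured
    onset. The profile peak is normalized to 1, making ``noise_sd`` the
    per-channel noise amplitude relative to the evoked LFP peak. The noise
    is Gaussian in time but spatially correlated across contacts (Gaussian
    kernel, SD ``noise_spatial_sigma_ch`` contacts), emulating the high
    cross-contact coherence of ongoing LFP; spatially white noise would
    carry unrealistically large spatial curvature straight into the CSD.
    Returns ``(lfp, EventTable)``.
    """
    if n_trials < 1:
        raise ParameterError("need at least one trial")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_lfp
    n_per = int(round(trial_period_s * fs))
    n_total = n_per * n_trials
    profile, _ = _sink_lfp_profile(cfg.n_channels, tuple(sink_channels),
                                   cfg.spacing_um)
    t_rel = (np.arange(n_per) / fs) - event_offset_s
    t_peak = onset_s + sigma_s * np.sqrt(2 * np.log(2))
    course = np.exp(-((t_rel - t_peak) ** 2) / (2 * sigma_s**2))
    trial = profile[:, None] * course[None, :]
    lfp = np.tile(trial, (1, n_trials))
    if noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        noise = rng.standard_normal(lfp.shape)
        if noise_spatial_sigma_ch > 0:
            noise = gaussian_filter1d(noise, noise_spatial_sigma_ch, axis=0,
                                      mode="nearest")
            noise /= noise.std()
        lfp = lfp + noise_sd * noise
    onsets = event_offset_s + trial_period_s * np.arange(n_trials)
    return lfp, EventTable(onsets=onsets)
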