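"""Laminar spectral-power and firing-rate profiles.

Across cortical depth the LFP spectrum inverts: superficial layers carry
relatively more high-frequency (65-100 Hz) power and deep layers more
low-frequency (8-30 Hz) power, with the crossover near the input layer.
Band power is the Welch PSD averaged inside each band, normalized by the
across-channel, both-band mean, then z-scored across channels per band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, UndefinedResultError
from .io import LaminarRecording

__all__ = [
    "PowerProfile",
    "RateProfile",
    "band_power_profile",
    "power_crossover",
    "firing_rate_profile",
]


@dataclass
class PowerProfile:
    """Per-channel z-scored band power in a low and a high frequency band."""

    low_z: np.ndarray
    high_z: np.ndarray
    low_band: tuple
    high_band: tuple


class RateProfile(NamedTuple):
    normalized: np.ndarray
    mean_rate_hz: float
    defined: bool


def band_power_profile(lfp, fs, low=(8.0, 30.0), high=(65.0, 100.0),
                       segment_s: float = 1.0) -> PowerProfile:
    """Laminar profile of low- and high-band LFP power.

    PSD by Welch averaging (``segment_s`` Hann segments, 50% overlap). Each
    channel's mean PSD inside a band is normalized by the mean over all
    channels and both bands, then z-scored across channels (population SD),
    so the profile is invariant to a global gain.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=np.float64))
    for lo, hi in (low, high):
        if not 0 < lo < hi:
            raise ParameterError("bands must satisfy 0 < lo < hi")
        if hi >= fs / 2:
            raise ParameterError(f"band edge {hi} Hz at or above Nyquist {fs / 2}")
    if lfp.shape[1] < 2 * fs:
        raise ParameterError("need at least 2 s of data")
    nper = int(round(segment_s * fs))
    freqs, psd = sps.welch(lfp, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, axis=1)

    def band_mean(band):
        m = (freqs >= band[0]) & (freqs <= band[1])
        return psd[:, m].mean(axis=1)

    low_p = band_mean(low)
    high_p = band_mean(high)
    denom = 0.5 * (low_p.mean() + high_p.mean())
    low_n = low_p / denom
    high_n = high_p / denom

    def zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    return PowerProfile(zscore(low_n), zscore(high_n), tuple(low), tuple(high))


def power_crossover(profile: PowerProfile, depths):
    """Depth of the high-minus-low power sign flip.

    Scanning shallow to deep, the first transition of ``high_z - low_z``
    from positive to non-positive gives the crossover; the depth is linearly
    interpolated between the bracketing contacts. Returns ``(depth_um,
    detected)``; ``detected`` is False when no such crossing exists.
    """
    depths = np.asarray(depths, dtype=np.float64)
    if depths.size < 3:
        raise ParameterError("need at least 3 channels")
    d = profile.high_z - profile.low_z
    for i in range(d.size - 1):
        if d[i] > 0 and d[i + 1] <= 0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(depths[i] + frac * (depths[i + 1] - depths[i])), True
    return np.nan, False


def firing_rate_profile(rec: LaminarRecording) -> RateProfile:
    """Per-channel firing rate normalized to the all-channel mean rate."""
    dur = rec.duration_s
    if dur <= 0:
        raise ParameterError("recording has zero duration")
    rates = np.array([len(t) for t in rec.spikes], dtype=np.float64) / dur
    mean_rate = rates.mean()
    if mean_rate == 0:
        return RateProfile(np.full(rates.size, np.nan), 0.0, False)
    return RateProfile(rates / mean_rate, float(mean_rate), True)
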