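"""Evoked averaging, current-source density, and input-layer identification.

The CSD is the (negated) discrete second spatial derivative of the
stimulus-triggered average LFP across equally spaced contacts:
``CSD_i(t) = -(V_{i-1} - 2 V_i + V_{i+1}) / h^2``. With this sign
convention an evoked extracellular negativity — a current *sink*, where
positive charge flows into cells — is negative. Tissue conductivity is
folded into an arbitrary scale (sigma = 1, units uV/mm^2) because only the
relative spatial pattern matters for boundary finding. The earliest sink
marks the thalamorecipient input layer; its bottom channel is the reference
depth for the input/deep boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeError
from .io import EventTable

__all__ = [
    "CSDMap",
    "InputLayer",
    "evoked_average",
    "compute_csd",
    "find_input_layer",
    "assign_layers",
]


@dataclass
class CSDMap:
    """Current-source-density map on interior channels.

    ``csd[j]`` corresponds to original probe channel ``channels[j]`` (the
    first and last contact have no second difference). Sinks are negative.
    ``csd_smooth`` is a 4x depth-upsampled bicubic interpolation for
    display; detection always runs on the raw map.
    """

    csd: np.ndarray
    times: np.ndarray
    channels: np.ndarray
    spacing_um: float
    csd_smooth: np.ndarray | None = None


class InputLayer(NamedTuple):
    input_top: int
    input_bottom: int
    onset_latency_s: float
    detected: bool


def evoked_average(lfp, fs, events, window):
    """Baseline-subtracted stimulus-triggered LFP average.

    ``window = (pre_s, post_s)`` extends from ``pre_s`` before to ``post_s``
    after each event; the per-channel mean over the pre-event interval is
    subtracted. Events whose window leaves the record are dropped with a
    warning. Returns ``(erp, times)`` with times relative to the event.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=np.float64))
    onsets = events.onsets if isinstance(events, EventTable) else np.asarray(events)
    pre_s, post_s = window
    if pre_s < 0 or post_s <= 0:
        raise ParameterError("window must have pre_s >= 0 and post_s > 0")
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_samp = lfp.shape[1]
    acc = np.zeros((lfp.shape[0], n_pre + n_post))
    used = 0
    for t in onsets:
        i = int(round(t * fs))
        if i - n_pre < 0 or i + n_post > n_samp:
            warnings.warn(
                f"event at {t:.4f} s dropped: window leaves the record",
                stacklevel=2,
            )
            continue
        epoch = lfp[:, i - n_pre:i + n_post]
        if n_pre > 0:
            epoch = epoch - epoch[:, :n_pre].mean(axis=1, keepdims=True)
        acc += epoch
        used += 1
    if used == 0:
        raise ParameterError("no usable events inside the record")
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    return acc / used, times


def compute_csd(erp, spacing_um, times=None, smooth: bool = True) -> CSDMap:
    """CSD of a channels x time evoked response.

    Linear in the input; an affine-in-depth profile yields identically zero
    CSD on the interior channels.
    """
    erp = np.asarray(erp, dtype=np.float64)
    if erp.ndim != 2 or erp.shape[0] < 3:
        raise ShapeError("need a 2-D map with at least 3 channels")
    if spacing_um <= 0:
        raise ParameterError("spacing_um must be positive")
    h_mm = spacing_um / 1000.0
    second_diff = (erp[:-2] - 2 * erp[1:-1] + erp[2:]) / h_mm**2
    csd = -second_diff
    if times is None:
        times = np.arange(erp.shape[1], dtype=np.float64)
    smooth_map = None
    if smooth:
        smooth_map = ndimage.zoom(csd, (4, 1), order=3)
    return CSDMap(
        csd=csd,
        times=np.asarray(times, dtype=np.float64),
        channels=np.arange(1, erp.shape[0] - 1),
        spacing_um=float(spacing_um),
        csd_smooth=smooth_map,
    )


def find_input_layer(cmap: CSDMap, search_window=None,
                     threshold_frac: float = 0.5) -> InputLayer:
    """Earliest-sink detection on an (unsmoothed) CSD map.

    Sink channels are those whose minimum CSD inside the search window
    reaches ``threshold_frac`` of the global minimum; maximal contiguous
    runs form candidate sinks, each with onset at the first threshold
    crossing of any of its channels. The earliest-onset region is the input
    layer; channel indices are returned in original probe numbering.
    """
    if not 0 < threshold_frac <= 1:
        raise ParameterError("threshold_frac must be in (0, 1]")
    if search_window is None:
        t_mask = np.ones(cmap.times.size, dtype=bool)
    else:
        t0, t1 = search_window
        if t0 >= t1 or t0 < cmap.times[0] - 1e-12 or t1 > cmap.times[-1] + 1e-12:
            raise ParameterError("search window outside the map's time axis")
        t_mask = (cmap.times >= t0) & (cmap.times <= t1)
    sub = cmap.csd[:, t_mask]
    sub_times = cmap.times[t_mask]
    gmin = sub.min()
    if gmin >= 0:
        return InputLayer(-1, -1, np.nan, False)
    level = threshold_frac * gmin
    chan_hit = sub.min(axis=1) <= level
    if not chan_hit.any():
        return InputLayer(-1, -1, np.nan, False)
    # contiguous sink regions, each with its earliest crossing time
    best = None
    j = 0
    n = chan_hit.size
    while j < n:
        if not chan_hit[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and chan_hit[k + 1]:
            k += 1
        region = sub[j:k + 1]
        crossed = (region <= level).any(axis=0)
        onset = sub_times[np.argmax(crossed)]
        if best is None or onset < best[2]:
            best = (j, k, onset)
        j = k + 1
    top, bottom, onset = best
    return InputLayer(
        input_top=int(cmap.channels[top]),
        input_bottom=int(cmap.channels[bottom]),
        onset_latency_s=float(onset),
        detected=True,
    )


def assign_layers(depths, input_top: int, input_bottom: int):
    """Label each channel superficial / input / deep given the input-layer
    channel span. An input layer starting at the first contact leaves zero
    superficial channels (allowed)."""
    depths = np.asarray(depths)
    n = depths.size
    if not (0 <= input_top <= input_bottom < n):
        raise ParameterError(
            f"input span ({input_top}, {input_bottom}) invalid for {n} channels"
        )
    labels = np.empty(n, dtype=object)
    labels[:input_top] = "superficial"
    labels[input_top:input_bottom + 1] = "input"
    labels[input_bottom + 1:] = "deep"
    return list(labels)
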