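"""Reading and writing laminar recordings and result tables.

On-disk formats
---------------
Flat binary: ``<name>.bin`` holds the LFP as little-endian, channel-major
samples (all samples of channel 0, then channel 1, ...). A JSON sidecar
``<name>.json`` carries ``fs_lfp``, ``fs_raw``, ``n_channels``, ``dtype``,
``gain_uV_per_bit`` and ``channel_depths_um``. Spike times live in
``<name>.spikes.csv`` (columns ``channel,time_s``) and optional stimulus
onsets in ``<name>.events.csv`` (columns ``time_s,label``).

HDF5: a single file with datasets ``/lfp``, optional ``/raw``,
``/spikes/ch<k>`` and ``/events``, and root attributes mirroring the sidecar.

All voltages are microvolts, depths are micrometres increasing downward from
the most superficial contact, and times are seconds as 64-bit floats.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, ShapeError

SIDECAR_KEYS = ("fs_lfp", "n_channels", "dtype", "channel_depths_um")


@dataclass
class LaminarRecording:
    """A laminar probe session: LFP matrix, spike trains and geometry.

    Parameters
    ----------
    lfp : ndarray, shape (n_channels, n_samples)
        Local field potential in microvolts; row 0 is the most superficial
        contact.
    fs_lfp : float
        LFP sampling rate in Hz.
    channel_depths_um : ndarray
        Depth of each contact in micrometres, strictly increasing with index.
    spikes : list of ndarray
        Per-channel spike times in seconds, sorted ascending.
    raw : ndarray, optional
        Wideband signal (channels x samples) at ``fs_raw``, microvolts.
    events : ndarray, optional
        Stimulus onset times in seconds.
    meta : dict
        Free-form provenance.
    """

    lfp: np.ndarray
    fs_lfp: float
    channel_depths_um: np.ndarray
    spikes: list
    raw: np.ndarray | None = None
    fs_raw: float | None = None
    events: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp, dtype=np.float64)
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=np.float64)
        if self.lfp.ndim != 2:
            raise ShapeError("lfp must be a 2-D channels x samples array")
        if self.fs_lfp <= 0:
            raise FormatError("fs_lfp must be positive")
        n_ch = self.lfp.shape[0]
        if len(self.channel_depths_um) != n_ch:
            raise ShapeError(
                f"channel_depths_um has {len(self.channel_depths_um)} entries "
                f"for {n_ch} LFP channels"
            )
        if n_ch > 1 and not np.all(np.diff(self.channel_depths_um) > 0):
            raise FormatError("channel_depths_um must be strictly increasing")
        if len(self.spikes) != n_ch:
            raise ShapeError(
                f"{len(self.spikes)} spike trains for {n_ch} channels"
            )
        self.spikes = [np.sort(np.asarray(s, dtype=np.float64)) for s in self.spikes]
        dur = self.duration_s
        for k, s in enumerate(self.spikes):
            if s.size and (s[0] < 0 or s[-1] > dur):
                raise FormatError(
                    f"spike times on channel {k} fall outside [0, {dur:.6g}] s"
                )
        if self.events is not None:
            self.events = np.sort(np.asarray(self.events, dtype=np.float64))
            if self.events.size and self.events[0] < 0:
                raise FormatError("event onsets must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp

    @property
    def spacing_um(self) -> float:
        """Median inter-contact distance in micrometres."""
        return float(np.median(np.diff(self.channel_depths_um)))


@dataclass
class EventTable:
    """Stimulus onsets with free-text labels."""

    onsets: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if self.onsets.size and self.onsets[0] < 0:
            raise FormatError("event onsets must be non-negative")
        if not np.all(np.diff(self.onsets) >= 0):
            raise FormatError("event onsets must be sorted ascending")
        if self.labels is None:
            self.labels = [""] * self.onsets.size
        if len(self.labels) != self.onsets.size:
            raise ShapeError("labels length must match onsets")

    def __len__(self) -> int:
        return int(self.onsets.size)


def _read_sidecar(path: Path) -> dict:
    side = path.with_suffix(".json")
    if not side.exists():
        raise FormatError(f"sidecar metadata file not found: {side}")
    meta = json.loads(side.read_text())
    for key in SIDECAR_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar {side} is missing required key '{key}'")
    return meta


def _read_spike_csv(path: Path, n_channels: int) -> list:
    trains = [[] for _ in range(n_channels)]
    if path.exists():
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ch = int(row["channel"])
                if not 0 <= ch < n_channels:
                    raise FormatError(
                        f"spike channel {ch} out of range 0..{n_channels - 1}"
                    )
                trains[ch].append(float(row["time_s"]))
    return [np.asarray(t) for t in trains]


def _read_event_csv(path: Path):
    if not path.exists():
        return None
    onsets = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            onsets.append(float(row["time_s"]))
    return np.asarray(onsets)


def read_recording(path, format: str | None = None) -> LaminarRecording:
    """Read a recording from flat binary + sidecar or from HDF5.

    ``format`` is ``"flat_binary"`` or ``"hdf5"``; when omitted it is inferred
    from the file extension (``.h5``/``.hdf5`` -> HDF5).
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "flat_binary"
    if format == "hdf5":
        return _read_hdf5(path)
    if format != "flat_binary":
        raise FormatError(f"unknown format '{format}'")

    stem = path.with_suffix("") if path.suffix in (".bin", ".json") else path
    meta = _read_sidecar(stem.with_suffix(".json"))
    n_ch = int(meta["n_channels"])
    dtype = np.dtype(meta["dtype"]).newbyteorder("<")
    raw_bytes = stem.with_suffix(".bin").read_bytes()
    data = np.frombuffer(raw_bytes, dtype=dtype)
    if data.size % n_ch:
        raise ShapeError(
            f"{data.size} samples in {stem.with_suffix('.bin')} do not divide "
            f"into {n_ch} channels"
        )
    lfp = data.reshape(n_ch, -1).astype(np.float64)
    gain = float(meta.get("gain_uV_per_bit", 1.0) or 1.0)
    if dtype.kind in "iu":
        lfp *= gain
    spikes = _read_spike_csv(Path(str(stem) + ".spikes.csv"), n_ch)
    events = _read_event_csv(Path(str(stem) + ".events.csv"))
    return LaminarRecording(
        lfp=lfp,
        fs_lfp=float(meta["fs_lfp"]),
        fs_raw=meta.get("fs_raw"),
        channel_depths_um=np.asarray(meta["channel_depths_um"], dtype=float),
        spikes=spikes,
        events=events,
        meta={k: v for k, v in meta.items() if k not in SIDECAR_KEYS},
    )


def write_recording(rec: LaminarRecording, path, format: str | None = None,
                    dtype: str = "float32", gain_uV_per_bit: float = 1.0) -> None:
    """Write a recording in one of the documented formats.

    For integer ``dtype`` the LFP is quantized as ``round(uV / gain)``.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "flat_binary"
    if format == "hdf5":
        _write_hdf5(rec, path)
        return
    stem = path.with_suffix("") if path.suffix in (".bin", ".json") else path
    dt = np.dtype(dtype).newbyteorder("<")
    if dt.kind in "iu":
        payload = np.round(rec.lfp / gain_uV_per_bit).astype(dt)
    else:
        payload = rec.lfp.astype(dt)
    stem.with_suffix(".bin").write_bytes(payload.tobytes())
    sidecar = {
        "fs_lfp": rec.fs_lfp,
        "fs_raw": rec.fs_raw,
        "n_channels": rec.n_channels,
        "dtype": dtype,
        "gain_uV_per_bit": gain_uV_per_bit,
        "channel_depths_um": rec.channel_depths_um.tolist(),
        **rec.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    with open(str(stem) + ".spikes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "time_s"])
        for ch, train in enumerate(rec.spikes):
            for t in train:
                w.writerow([ch, repr(float(t))])
    if rec.events is not None:
        with open(str(stem) + ".events.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "label"])
            for t in rec.events:
                w.writerow([repr(float(t)), ""])


def _write_hdf5(rec: LaminarRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp.astype(np.float64))
        if rec.raw is not None:
            f.create_dataset("raw", data=rec.raw)
        g = f.create_group("spikes")
        for ch, train in enumerate(rec.spikes):
            g.create_dataset(f"ch{ch}", data=train)
        if rec.events is not None:
            f.create_dataset("events", data=rec.events)
        f.attrs["fs_lfp"] = rec.fs_lfp
        if rec.fs_raw is not None:
            f.attrs["fs_raw"] = rec.fs_raw
        f.attrs["n_channels"] = rec.n_channels
        f.attrs["channel_depths_um"] = rec.channel_depths_um
        f.attrs["meta_json"] = json.dumps(rec.meta)


def _read_hdf5(path: Path) -> LaminarRecording:
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise FormatError(f"{path} has no /lfp dataset")
        for key in ("fs_lfp", "n_channels", "channel_depths_um"):
            if key not in f.attrs:
                raise FormatError(f"{path} is missing required attribute '{key}'")
        lfp = f["lfp"][()]
        n_ch = int(f.attrs["n_channels"])
        if lfp.shape[0] != n_ch:
            raise ShapeError(
                f"/lfp has {lfp.shape[0]} rows but n_channels={n_ch}"
            )
        spikes = [
            f["spikes"][f"ch{k}"][()] if "spikes" in f and f"ch{k}" in f["spikes"]
            else np.empty(0)
            for k in range(n_ch)
        ]
        return LaminarRecording(
            lfp=lfp,
            fs_lfp=float(f.attrs["fs_lfp"]),
            fs_raw=float(f.attrs["fs_raw"]) if "fs_raw" in f.attrs else None,
            raw=f["raw"][()] if "raw" in f else None,
            channel_depths_um=np.asarray(f.attrs["channel_depths_um"]),
            spikes=spikes,
            events=f["events"][()] if "events" in f else None,
            meta=json.loads(f.attrs.get("meta_json", "{}")),
        )


def _matrix_tsv(path: Path, header: np.ndarray, rows: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(f"{d:.6g}" for d in header) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def write_results(result, path) -> None:
    """Write a result object to disk.

    Matrices (``LPCMatrix``, ``CSDMap``, ``PowerProfile``) become TSV with a
    channel-depth header row; estimates and tables become JSON. Raises
    ``TypeError`` for unsupported objects.
    """
    from .coupling import LaminarEstimate, LPCMatrix
    from .csd import CSDMap
    from .power import PowerProfile

    path = Path(path)
    if isinstance(result, LPCMatrix):
        _matrix_tsv(path.with_suffix(".spi.tsv"), result.depths, result.spi)
        _matrix_tsv(path.with_suffix(".angle.tsv"), result.depths, result.angle)
    elif isinstance(result, CSDMap):
        _matrix_tsv(path, result.times, result.csd)
    elif isinstance(result, PowerProfile):
        with open(path, "w") as fh:
            fh.write("low_z\thigh_z\n")
            for lo, hi in zip(result.low_z, result.high_z):
                fh.write(f"{lo:.10g}\t{hi:.10g}\n")
    elif isinstance(result, LaminarEstimate):
        path.write_text(json.dumps(dataclasses.asdict(result), indent=1))
    elif isinstance(result, EventTable):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "label"])
            for t, lab in zip(result.onsets, result.labels):
                w.writerow([repr(float(t)), lab])
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def read_estimate(path):
    """Read back a ``LaminarEstimate`` written by :func:`write_results`."""
    from .coupling import LaminarEstimate

    return LaminarEstimate(**json.loads(Path(path).read_text()))
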