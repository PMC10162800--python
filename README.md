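# lpc — laminar-phase-coupling analysis for linear-array recordings

`lpc` locates the boundary between the input (granular) and deep
(infragranular) cortical layers on laminar probe recordings from the
structure of *ongoing* activity, and ships the classical diagnostics used to
validate that estimate: current-source-density (CSD) analysis of evoked
responses, laminar spectral-power profiles, firing-rate profiles, and the
circular statistics that tie them together. It is written for
electrophysiologists working with multi-channel linear arrays (e.g.
32-contact probes at ~100 µm spacing) who need reliable layer assignment
without depending on a stimulus-evoked CSD — and who want to track probe
drift within a session.

## The method

Multi-unit spikes throughout the cortical column prefer the trough (±π) of
the local field potential measured on superficial and input-layer contacts,
but the peak (0 rad) of the LFP measured on deep contacts. The package

1. computes the **generalized phase** (GP) of each channel: the analytic
   signal of the wideband-filtered LFP (5–50 Hz, fourth-order Butterworth
   forward-reverse), with epochs of negative instantaneous frequency —
   complex riding cycles caused by high-frequency intrusions — repaired by
   shape-preserving cubic interpolation;
2. builds the **laminar-phase-coupling (LPC) matrix**: for every spike
   channel r and LFP channel c, the spike-phase index
   `SPI(r, c) = |⟨e^{iφ_c(t_spike)}⟩|` (the mean resultant length of the LFP
   phases at spike times, 0 = uniform, 1 = perfectly locked) and the
   preferred angle `⟨φ⟩`;
3. detects the depth at which the column-wise preferred angle **reverses by
   ~π**: for each cut k between channels, it scores
   `R_above·R_below·|circ_dist(μ_above, μ_below)|` over the SPI-weighted
   column angle profile and takes the argmax. The estimate comes with a
   reversal-strength score (angular separation / π) and a validity flag
   (separation ≥ π/2).

Because the method needs no trigger — a minute of data and a few hundred
spikes per channel suffice — it can be recomputed on sequential 3-minute
epochs to measure electrode drift.

A synthetic-recording generator (`lpc.synth`) produces sessions with a known
boundary, layer-dependent von Mises spike–phase coupling, 1/f background,
a laminar spectral gradient, optional drift, and evoked sink/source trials,
so the whole pipeline is testable with ground truth.

## Worked example

```bash
lpc simulate --seed 1 --duration-s 120 --out sess1
lpc estimate sess1.bin --out sess1
lpc power sess1.bin --out sess1
```

prints

```
wrote sess1.bin (32 ch, 120 s)
boundary channel 15 (1500 um), strength 0.98, valid=True
power crossover: 1551.5318534646567
```

and writes `sess1.estimate.json`:

```json
{
 "boundary_channel": 15,
 "boundary_depth_um": 1500.0,
 "reversal_strength": 0.9845175630095171,
 "valid": true,
 "method": "lpc"
}
```

The simulated session put its phase flip at channel 15 (0-based; 1500 µm
below the most superficial contact). The LPC estimate recovers exactly that
channel with a reversal strength of 0.98 — the preferred angles above and
below the cut are separated by 0.98·π radians, far above the π/2 validity
threshold. The high/low band-power crossover lands at 1551 µm, within one
contact spacing of the same boundary, as expected when the spectral
inversion and the phase flip share a cause. `sess1.spi.tsv` /
`sess1.angle.tsv` hold the full 32×32 coupling matrices.

The same pipeline runs from Python:

```python
from lpc import (SynthConfig, generate_recording, compute_generalized_phase,
                 lpc_matrix, detect_phase_reversal)

rec, truth = generate_recording(SynthConfig(duration_s=120.0, seed=1))
gp = compute_generalized_phase(rec.lfp, rec.fs_lfp)          # phase per channel
est = detect_phase_reversal(lpc_matrix(rec, gp))             # boundary estimate
print(est.boundary_channel, truth["boundary_channel"])       # -> 15 15
```

Other subcommands: `lpc csd` (evoked CSD + earliest-sink input-layer
bounds), `lpc drift` (epoch-wise boundary series), `lpc mua`
(threshold-crossing spike detection on wideband data), `lpc gp`, and
`lpc report` (everything, with provenance). Recordings are accepted as flat
binary + JSON sidecar or HDF5; spikes and events as CSV.

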