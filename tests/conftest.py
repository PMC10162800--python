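import numpy as np
import pytest

from lpc.io import LaminarRecording
from lpc.signal import compute_generalized_phase
from lpc.synth import SynthConfig, generate_recording


def bessel_ratio(kappa: float, terms: int = 40) -> float:
    """I1(kappa)/I0(kappa) by direct power-series summation.

    Independent oracle for the mean resultant length of a von Mises
    distribution: I_nu(x) = sum_k (x/2)^(2k+nu) / (k! * (k+nu)!).
    """
    half = kappa / 2.0
    i0 = i1 = 0.0
    fact = 1.0
    for k in range(terms):
        if k > 0:
            fact *= k
        i0 += half ** (2 * k) / (fact * fact)
        i1 += half ** (2 * k + 1) / (fact * fact * (k + 1))
    return i1 / i0


@pytest.fixture(scope="session")
def short_session():
    """A 120 s default-parameter synthetic session plus its GP, shared by
    coupling-level tests."""
    cfg = SynthConfig(duration_s=120.0, boundary_channel=15, seed=1)
    rec, truth = generate_recording(cfg)
    gp = compute_generalized_phase(rec.lfp, rec.fs_lfp)
    return rec, gp, truth


@pytest.fixture
def tiny_recording():
    """4-channel, 1 s, 1 kHz recording with a few spikes."""
    rng = np.random.default_rng(0)
    lfp = rng.standard_normal((4, 1000)).astype(np.float32).astype(np.float64)
    return LaminarRecording(
        lfp=lfp,
        fs_lfp=1000.0,
        channel_depths_um=np.array([0.0, 100.0, 200.0, 300.0]),
        spikes=[np.array([0.1, 0.5]), np.array([0.25]), np.empty(0),
                np.array([0.33, 0.66, 0.99])],
        events=np.array([0.2, 0.7]),
        meta={"origin": "fixture"},
    )
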