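import numpy as np
import pytest

from conftest import bessel_ratio
from lpc.circstats import circ_dist, wrap_angle
from lpc.coupling import (LPCMatrix, align_and_average, detect_phase_reversal,
                          lpc_matrix, lpc_over_epochs, spike_phase_stats)
from lpc.errors import EstimationError, ParameterError
from lpc.io import LaminarRecording
from lpc.signal import GPResult, compute_generalized_phase
from lpc.synth import SynthConfig, generate_recording


def matrix_from_profile(col_angles, n_rows=None, spi=0.3):
    """LPCMatrix whose every valid row shows the given column angle profile."""
    col_angles = np.asarray(col_angles, dtype=float)
    n = col_angles.size
    rows = n if n_rows is None else n_rows
    return LPCMatrix(
        spi=np.full((rows, n), spi),
        angle=np.tile(col_angles, (rows, 1)),
        n_spikes=np.full(rows, 1000),
        depths=np.arange(n) * 100.0,
        valid_rows=np.ones(rows, bool),
    )


class TestSpikePhaseStats:
    def test_perfectly_locked_spikes(self):
        fs = 1000.0
        phase = np.zeros(1000)
        idx = np.array([100, 300, 700])
        phase[idx] = np.pi / 2
        st = spike_phase_stats(idx / fs, phase, fs)
        assert st.spi == pytest.approx(1.0)
        assert st.mean_angle == pytest.approx(np.pi / 2)
        assert st.n_spikes == 3

    def test_von_mises_phases_give_bessel_ratio_spi(self):
        rng = np.random.default_rng(21)
        n = 5000
        phase = wrap_angle(rng.vonmises(np.pi, 1.0, size=n))
        st = spike_phase_stats(np.arange(n) / 1000.0, phase, 1000.0)
        assert st.spi == pytest.approx(bessel_ratio(1.0), abs=0.02)
        assert bessel_ratio(1.0) == pytest.approx(0.4464, abs=1e-4)

    def test_random_spikes_against_noise_phase_uncoupled(self):
        rng = np.random.default_rng(22)
        spec = rng.standard_normal(30001) + 1j * rng.standard_normal(30001)
        freqs = np.maximum(np.fft.rfftfreq(60000, 1e-3), 1.0)
        x = np.fft.irfft(spec / np.sqrt(freqs), n=60000)
        gp = compute_generalized_phase(x, 1000.0)
        t = rng.uniform(0, 59.9, 10000)
        st = spike_phase_stats(t, gp.phase[0], 1000.0)
        assert st.spi < 0.03

    def test_zero_spikes_flagged(self):
        st = spike_phase_stats(np.empty(0), np.zeros(100), 1000.0)
        assert st.n_spikes == 0 and not st.defined

    def test_out_of_range_spikes_rejected(self):
        with pytest.raises(ParameterError):
            spike_phase_stats(np.array([2.0]), np.zeros(100), 1000.0)


class TestLpcMatrix:
    def test_identical_channels_give_identical_cells(self):
        rng = np.random.default_rng(23)
        row = rng.standard_normal(4000)
        lfp = np.tile(row, (4, 1))
        spikes = [np.sort(rng.uniform(0, 3.9, 400))] * 4
        rec = LaminarRecording(lfp=lfp, fs_lfp=1000.0,
                               channel_depths_um=np.arange(4) * 100.0,
                               spikes=spikes)
        gp = compute_generalized_phase(lfp, 1000.0)
        m = lpc_matrix(rec, gp, min_spikes=100)
        assert np.ptp(m.spi) < 1e-12
        assert np.ptp(m.angle) < 1e-12

    def test_diagonal_matches_within_channel_stats(self, short_session):
        rec, gp, _ = short_session
        m = lpc_matrix(rec, gp, min_spikes=100)
        for ch in (0, 15, 31):
            st = spike_phase_stats(rec.spikes[ch], gp.phase[ch], gp.fs)
            assert m.spi[ch, ch] == pytest.approx(st.spi, abs=1e-12)
            assert m.angle[ch, ch] == pytest.approx(st.mean_angle, abs=1e-12)

    def test_angle_pattern_antipodal_across_boundary(self):
        # on a noiseless drive every valid cell's preferred angle sits near
        # +-pi against superficial/input LFP and near 0 against deep LFP;
        # the angle SE scales as 1/(kappa*sqrt(n)), so the weakly coupled
        # deep rows (kappa 0.15) need a few thousand spikes for a pi/4 bound
        cfg = SynthConfig(duration_s=240.0, noise_sd=0.0, spectral_gradient=0.0,
                          rate_sup=10.0, rate_in=10.0, rate_deep=10.0, seed=1)
        rec, truth = generate_recording(cfg)
        gp = compute_generalized_phase(rec.lfp, rec.fs_lfp)
        m = lpc_matrix(rec, gp, min_spikes=100)
        b = truth["boundary_channel"]
        for r in np.flatnonzero(m.valid_rows):
            above = m.angle[r, :b + 1]
            below = m.angle[r, b + 1:]
            assert np.all(np.abs(circ_dist(above, np.pi)) < np.pi / 4)
            assert np.all(np.abs(circ_dist(below, 0.0)) < np.pi / 4)


class TestDetectPhaseReversal:
    def test_noiseless_antipodal_profile(self):
        # channels 0..15 prefer pi, 16..31 prefer 0 -> boundary at 15
        profile = np.r_[np.full(16, np.pi), np.zeros(16)]
        est = detect_phase_reversal(matrix_from_profile(profile))
        assert est.boundary_channel == 15
        assert est.reversal_strength == pytest.approx(1.0)
        assert est.valid

    def test_uniform_profile_invalid(self):
        est = detect_phase_reversal(matrix_from_profile(np.full(32, np.pi)))
        assert not est.valid

    def test_rotation_invariance(self):
        rng = np.random.default_rng(24)
        profile = wrap_angle(np.r_[np.full(20, np.pi), np.zeros(12)]
                             + 0.2 * rng.standard_normal(32))
        base = detect_phase_reversal(matrix_from_profile(profile))
        for rot in (0.7, -2.1, np.pi):
            m = matrix_from_profile(wrap_angle(profile + rot))
            est = detect_phase_reversal(m)
            assert est.boundary_channel == base.boundary_channel
            assert est.reversal_strength == pytest.approx(
                base.reversal_strength, abs=1e-9)

    def test_synthetic_recovery(self, short_session):
        rec, gp, truth = short_session
        m = lpc_matrix(rec, gp, min_spikes=100)
        est = detect_phase_reversal(m)
        assert abs(est.boundary_channel - truth["boundary_channel"]) <= 1
        assert est.valid

    def test_too_few_valid_rows(self):
        m = matrix_from_profile(np.r_[np.full(8, np.pi), np.zeros(8)])
        m.valid_rows[:] = False
        m.valid_rows[0] = True
        with pytest.raises(EstimationError):
            detect_phase_reversal(m)


class TestEpochsAndAveraging:
    def test_window_longer_than_record_rejected(self, short_session):
        rec, gp, _ = short_session
        with pytest.raises(ParameterError):
            lpc_over_epochs(rec, gp, window_s=600.0)

    def test_stationary_epochs_agree(self, short_session):
        rec, gp, truth = short_session
        series = lpc_over_epochs(rec, gp, window_s=40.0, step_s=40.0,
                                 min_spikes=50)
        boundaries = [e.boundary_channel for _, e in series]
        assert len(series) == 3
        assert all(abs(b - truth["boundary_channel"]) <= 1 for b in boundaries)
        assert max(boundaries) - min(boundaries) <= 1

    def test_single_session_average_is_identity(self):
        profile = np.r_[np.full(16, np.pi), np.zeros(16)]
        m = matrix_from_profile(profile)
        est = detect_phase_reversal(m)
        rel, spi_mean, angle_mean, cov = align_and_average([m], [est])
        assert rel[0] == -est.boundary_channel
        np.testing.assert_allclose(spi_mean, m.spi)
        np.testing.assert_allclose(angle_mean, m.angle, atol=1e-12)

    def test_two_offset_sessions_overlap(self):
        p1 = np.r_[np.full(16, np.pi), np.zeros(16)]
        p2 = np.r_[np.full(17, np.pi), np.zeros(15)]
        m1, m2 = matrix_from_profile(p1), matrix_from_profile(p2)
        e1, e2 = detect_phase_reversal(m1), detect_phase_reversal(m2)
        assert (e1.boundary_channel, e2.boundary_channel) == (15, 16)
        rel, spi_mean, angle_mean, cov = align_and_average([m1, m2], [e1, e2])
        # in the overlap both sessions contribute; the angle split must sit
        # exactly at relative depth 0
        zero = np.flatnonzero(rel == 0)[0]
        overlap = cov == 2
        assert overlap.any()
        cols = np.flatnonzero(overlap.any(axis=0))
        for c in cols:
            expected = np.pi if c <= zero else 0.0
            col_vals = angle_mean[overlap[:, c], c]
            assert np.all(np.abs(circ_dist(col_vals, expected)) < 1e-9)

    def test_mixed_spacing_rejected(self):
        m1 = matrix_from_profile(np.r_[np.full(8, np.pi), np.zeros(8)])
        m2 = matrix_from_profile(np.r_[np.full(8, np.pi), np.zeros(8)])
        m2.depths = m2.depths * 2
        e = detect_phase_reversal(m1)
        with pytest.raises(ParameterError):
            align_and_average([m1, m2], [e, e])


def test_drift_schedule_recovered():
    cfg = SynthConfig(duration_s=360.0, boundary_channel=16, seed=31,
                      drift_schedule=[(0, 16), (180, 18)])
    rec, _ = generate_recording(cfg)
    gp = compute_generalized_phase(rec.lfp, rec.fs_lfp)
    series = lpc_over_epochs(rec, gp, window_s=90.0, step_s=90.0, min_spikes=100)
    first, last = series[0][1], series[-1][1]
    assert last.boundary_channel - first.boundary_channel == 2
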