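import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bessel_ratio
from lpc.circstats import (circ_corr_cc, circ_corr_cl, circ_dist,
                           circ_mean_resultant, watson_williams, wrap_angle)
from lpc.errors import ParameterError, UndefinedResultError


class TestMeanResultant:
    def test_degenerate_point_mass(self):
        ma, r, defined = circ_mean_resultant(np.full(7, np.pi / 2))
        assert (ma, r, defined) == (pytest.approx(np.pi / 2), pytest.approx(1.0), True)

    def test_antipodal_cancellation_flagged(self):
        res = circ_mean_resultant(np.array([0.0, np.pi]))
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert not res.defined

    def test_two_orthogonal_angles(self):
        ma, r, _ = circ_mean_resultant(np.array([0.0, np.pi / 2]))
        assert ma == pytest.approx(np.pi / 4)
        assert r == pytest.approx(np.sqrt(2) / 2, abs=1e-9)  # |(1,1)|/2

    def test_empty_sample_rejected(self):
        with pytest.raises(UndefinedResultError):
            circ_mean_resultant(np.empty(0))

    def test_weights(self):
        # weight 0 removes an angle entirely
        ma, r, _ = circ_mean_resultant(np.array([0.0, np.pi]),
                                       weights=np.array([1.0, 0.0]))
        assert (ma, r) == (pytest.approx(0.0), pytest.approx(1.0))

    @given(st.floats(-np.pi, np.pi), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rotation_equivariance(self, rot, seed):
        angles = np.random.default_rng(seed).vonmises(0.5, 2.0, size=50)
        base = circ_mean_resultant(angles)
        moved = circ_mean_resultant(wrap_angle(angles + rot))
        assert moved.r == pytest.approx(base.r, abs=1e-12)
        assert abs(circ_dist(moved.mean_angle, base.mean_angle + rot)) < 1e-9

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
    def test_von_mises_resultant_matches_bessel_ratio(self, kappa):
        n = 5000
        rng = np.random.default_rng(int(kappa * 10))
        angles = rng.vonmises(0.0, kappa, size=n)
        r = circ_mean_resultant(angles).r
        expected = bessel_ratio(kappa)
        se = np.sqrt((1 - expected**2) / (2 * n))
        assert abs(r - expected) < 3 * se


class TestCircDist:
    @pytest.mark.parametrize("a,b,d", [(0, 0, 0), (np.pi / 2, 0, np.pi / 2),
                                       (-np.pi + 0.1, np.pi - 0.1, 0.2)])
    def test_examples(self, a, b, d):
        assert circ_dist(a, b) == pytest.approx(d)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_antisymmetric(self, a, b):
        d = circ_dist(a, b)
        assert -np.pi < d <= np.pi
        if abs(abs(d) - np.pi) > 1e-9:
            assert circ_dist(b, a) == pytest.approx(-d, abs=1e-9)


def _permutation_ww_p(groups, n_perm=10_000, seed=0):
    """Permutation null for the Watson-Williams F: shuffle group labels,
    recompute the statistic, report the upper-tail proportion."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    f_obs = watson_williams(groups).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if watson_williams(parts).statistic >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestWatsonWilliams:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        g = rng.vonmises(0.0, 5.0, size=50)
        res = watson_williams([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.4

    def test_opposed_means_significant(self):
        rng = np.random.default_rng(6)
        a = rng.vonmises(0.0, 5.0, size=50)
        b = wrap_angle(rng.vonmises(0.0, 5.0, size=50) + np.pi)
        assert watson_williams([a, b]).p < 0.001

    def test_hand_computed_three_vs_three(self):
        g1 = np.array([0.0, 0.2, -0.1])
        g2 = np.array([1.0, 1.2, 0.9])
        # textbook formula, spelled out step by step
        r1 = abs(np.exp(1j * g1).sum())
        r2 = abs(np.exp(1j * g2).sum())
        r_tot = abs(np.exp(1j * np.concatenate([g1, g2])).sum())
        rw = (r1 + r2) / 6
        kappa = 1 / (rw**3 - 4 * rw**2 + 3 * rw)  # rw > 0.85 branch
        f_hand = (1 + 3 / (8 * kappa)) * (6 - 2) * (r1 + r2 - r_tot) / (
            (2 - 1) * (6 - (r1 + r2)))
        res = watson_williams([g1, g2])
        assert res.statistic == pytest.approx(f_hand, rel=1e-9)
        assert res.statistic == pytest.approx(62.9535, rel=1e-4)

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="0.45"):
            res = watson_williams([rng.uniform(-np.pi, np.pi, 40),
                                   rng.uniform(-np.pi, np.pi, 40)])
        assert res.warning is not None

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_agrees_with_permutation_null(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(0, 0.8)
        a = rng.vonmises(0.0, 3.0, size=40)
        b = wrap_angle(rng.vonmises(0.0, 3.0, size=40) + mu)
        res = watson_williams([a, b])
        p_perm = _permutation_ww_p([a, b], n_perm=10_000, seed=seed)
        assert abs(res.p - p_perm) < 0.03

    def test_too_few_groups_rejected(self):
        with pytest.raises(ParameterError):
            watson_williams([np.array([0.0, 1.0])])


class TestCircCorrCC:
    def test_self_and_rotation(self):
        a = np.random.default_rng(9).vonmises(0.0, 2.0, size=500)
        assert circ_corr_cc(a, a).r == pytest.approx(1.0, abs=1e-9)
        assert circ_corr_cc(a, wrap_angle(a + 1.0)).r == pytest.approx(1.0, abs=1e-9)

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(-np.pi, np.pi, 2000)
        b = rng.uniform(-np.pi, np.pi, 2000)
        res = circ_corr_cc(a, b)
        assert abs(res.r) < 0.05
        assert res.p > 0.01

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        a = rng.vonmises(0.0, 1.5, size=200)
        b = wrap_angle(a + 0.4 * rng.standard_normal(200))
        ours = circ_corr_cc(a, b)
        theirs_r, theirs_p = pingouin.circ_corrcc(a, b)
        assert ours.r == pytest.approx(theirs_r, abs=1e-9)
        assert ours.p == pytest.approx(theirs_p, abs=1e-6)

    def test_degenerate_flagged(self):
        assert not circ_corr_cc(np.zeros(10), np.linspace(-1, 1, 10)).defined


class TestCircCorrCL:
    def test_cosine_relation_detected(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(-np.pi, np.pi, 1000)
        res = circ_corr_cl(a, np.cos(a))
        assert res.r > 0.99
        assert res.p < 1e-6

    def test_independent_near_zero(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(-np.pi, np.pi, 2000)
        x = rng.standard_normal(2000)
        assert circ_corr_cl(a, x).r < 0.06

    def test_range_and_pingouin_agreement(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        for _ in range(5):
            a = rng.uniform(-np.pi, np.pi, 100)
            x = rng.standard_normal(100)
            res = circ_corr_cl(a, x)
            assert 0.0 <= res.r <= 1.0
            theirs_r, theirs_p = pingouin.circ_corrcl(a, x)
            assert res.r == pytest.approx(theirs_r, abs=1e-9)
            assert res.p == pytest.approx(theirs_p, abs=1e-6)

    def test_constant_x_flagged(self):
        assert not circ_corr_cl(np.linspace(-3, 3, 10), np.ones(10)).defined
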