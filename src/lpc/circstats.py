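"""Circular statistics: resultant vectors, Watson-Williams test, and
circular-circular / circular-linear correlation.

Angles are radians wrapped to (-pi, pi]. Weighted means are supported
because the boundary detector aggregates coupling-matrix columns with
per-cell weights.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedResultError

__all__ = [
    "wrap_angle",
    "circ_mean_resultant",
    "circ_dist",
    "watson_williams",
    "circ_corr_cc",
    "circ_corr_cl",
]

_R_UNDEFINED = 1e-9


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(a, dtype=np.float64)))


class MeanResultant(NamedTuple):
    mean_angle: float
    r: float
    defined: bool


class TestResult(NamedTuple):
    statistic: float
    p: float
    warning: str | None = None


class CorrResult(NamedTuple):
    r: float
    p: float
    defined: bool = True


def circ_mean_resultant(angles, weights=None) -> MeanResultant:
    """Weighted circular mean direction and mean resultant length.

    R = |sum w * exp(i*theta)| / sum w, in [0, 1]; the mean angle is the
    argument of the vector sum. When the resultant vanishes (e.g. antipodal
    angles) the mean direction is undefined and flagged.
    """
    angles = np.asarray(angles, dtype=np.float64)
    if angles.size == 0:
        raise UndefinedResultError("circular mean of an empty sample")
    if weights is None:
        weights = np.ones_like(angles)
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != angles.shape:
            raise ParameterError("weights must match angles in shape")
        if (weights < 0).any():
            raise ParameterError("weights must be non-negative")
    wsum = weights.sum()
    if wsum <= 0:
        raise UndefinedResultError("all weights are zero")
    z = np.sum(weights * np.exp(1j * angles)) / wsum
    r = float(np.abs(z))
    defined = r > _R_UNDEFINED
    return MeanResultant(float(np.angle(z)) if defined else np.nan, r, defined)


def circ_dist(a, b):
    """Signed shortest angular difference wrap(a - b), in (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a, dtype=np.float64) - np.asarray(b))))


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood von Mises concentration from a mean resultant
    length (Fisher's approximation)."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(groups) -> TestResult:
    """Watson-Williams test of homogeneity of circular means.

    The circular one-way ANOVA: under a common von Mises concentration the
    statistic K * (N - k)(sum_j R_j - R) / ((k - 1)(N - sum_j R_j)) follows
    an F(k-1, N-k) distribution, where R_j are within-group resultant
    magnitudes, R the pooled resultant magnitude, and K = 1 + 3/(8*kappa)
    the small-concentration correction. A warning is attached when any
    group's mean resultant length falls below 0.45 (test assumption
    violated).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ParameterError("each group needs at least two angles")
    k = len(groups)
    n = sum(g.size for g in groups)
    zs = [np.sum(np.exp(1j * g)) for g in groups]
    r_mags = np.array([np.abs(z) for z in zs])
    r_tot = np.abs(np.sum(zs))
    warning = None
    if np.any(r_mags / np.array([g.size for g in groups]) < 0.45):
        warning = (
            "a group mean resultant length is below 0.45; the Watson-Williams "
            "assumptions are violated and the p-value is unreliable"
        )
        warnings.warn(warning, stacklevel=2)
    rw = r_mags.sum() / n
    kappa = _kappa_from_r(rw)
    corr = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = n - r_mags.sum()
    if denom <= 0:
        return TestResult(np.inf, 0.0, warning)
    f_stat = corr * ((n - k) * (r_mags.sum() - r_tot)) / ((k - 1) * denom)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    return TestResult(float(f_stat), p, warning)


def circ_corr_cc(a, b) -> CorrResult:
    """Jammalamadaka-SenGupta circular-circular correlation.

    r = sum sin(a - abar) sin(b - bbar) /
        sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar)),
    with a large-sample normal approximation for the p-value. Returns an
    undefined-result flag when either sample has zero angular variance.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 3:
        raise ParameterError("samples must have equal length >= 3")
    abar = circ_mean_resultant(a).mean_angle
    bbar = circ_mean_resultant(b).mean_angle
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    den = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if den < 1e-12 or not np.isfinite(den):
        return CorrResult(np.nan, np.nan, defined=False)
    r = float(np.sum(sa * sb) / den)
    n = a.size
    l20 = np.mean(sa**2)
    l02 = np.mean(sb**2)
    l22 = np.mean(sa**2 * sb**2)
    if l22 <= 0:
        return CorrResult(r, np.nan, defined=False)
    z = np.sqrt(n * l20 * l02 / l22) * r
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrResult(r, p)


def circ_corr_cl(a, x) -> CorrResult:
    """Circular-linear correlation (Mardia).

    r = sqrt((r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2)) with
    r_cx = corr(cos a, x), r_sx = corr(sin a, x), r_cs = corr(cos a, sin a);
    p from the chi-squared(2) approximation of n*r^2.
    """
    a = np.asarray(a, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if a.shape != x.shape or a.size < 4:
        raise ParameterError("samples must have equal length >= 4")
    if np.std(x) < 1e-12:
        return CorrResult(np.nan, np.nan, defined=False)
    c, s = np.cos(a), np.sin(a)
    rcx = np.corrcoef(c, x)[0, 1]
    rsx = np.corrcoef(s, x)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    num = rcx**2 + rsx**2 - 2 * rcx * rsx * rcs
    r2 = num / (1 - rcs**2)
    r = float(np.sqrt(np.clip(r2, 0.0, 1.0)))
    n = a.size
    p = float(stats.chi2.sf(n * r**2, 2))
    return CorrResult(r, p)
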