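"""Two-sample two-dimensional Kolmogorov-Smirnov test.

Fasano-Franceschini form: every data point of each sample is taken as a
quadrant origin; the statistic D is the mean of the two per-sample
maxima of the absolute difference between the samples' quadrant
fractions.  Quadrants are open — points lying exactly on a dividing
line (including the origin itself) are excluded from all four counts,
while the fractions keep the full sample sizes as denominators.

The asymptotic p-value follows the Numerical-Recipes treatment with
effective size n1*n2/(n1+n2) and a sqrt(1-r^2) correlation correction;
a label-permutation mode provides the exact-resampling reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DomainError


@dataclass(frozen=True)
class KS2DResult:
    D: float
    p: float
    n1: int
    n2: int
    method: str
    r_corr: float


def _as_points(s) -> np.ndarray:
    pts = np.asarray(s, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("samples must be (n, 2) point sets")
    if pts.shape[0] < 3:
        raise DomainError("each sample needs at least 3 points")
    return pts


def _quadrant_matrices(points: np.ndarray):
    """Boolean (n_origins, n_points) membership matrices for the four
    open quadrants around every point taken as origin."""
    x, y = points[:, 0], points[:, 1]
    gx = x[None, :] > x[:, None]
    lx = x[None, :] < x[:, None]
    gy = y[None, :] > y[:, None]
    ly = y[None, :] < y[:, None]
    quads = [(gx & gy), (lx & gy), (lx & ly), (gx & ly)]
    mats = [q.astype(np.float64) for q in quads]
    rowsums = [m.sum(axis=1) for m in mats]
    return mats, rowsums


def _D_from_labels(quadrants, in1: np.ndarray, n1: int, n2: int) -> float:
    """D given a boolean sample-1 membership vector over pooled points."""
    mats, rowsums = quadrants
    maxdiff = np.zeros(in1.shape[0])
    f1 = in1.astype(np.float64)
    for Q, ctot in zip(mats, rowsums):
        c1 = Q @ f1
        diff = np.abs(c1 / n1 - (ctot - c1) / n2)
        np.maximum(maxdiff, diff, out=maxdiff)
    d1 = maxdiff[in1].max()
    d2 = maxdiff[~in1].max()
    return 0.5 * float(d1 + d2)


def _pooled(s1, s2):
    p1, p2 = _as_points(s1), _as_points(s2)
    pooled = np.concatenate([p1, p2], axis=0)
    in1 = np.zeros(len(pooled), dtype=bool)
    in1[: len(p1)] = True
    return pooled, in1, len(p1), len(p2)


def ks2d_statistic(s1, s2) -> float:
    """Fasano-Franceschini D between two (n, 2) samples."""
    pooled, in1, n1, n2 = _pooled(s1, s2)
    return _D_from_labels(_quadrant_matrices(pooled), in1, n1, n2)


def _pooled_correlation(s1, s2) -> float:
    rs = []
    for pts in (np.asarray(s1, float), np.asarray(s2, float)):
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
        rs.append(0.0 if not np.isfinite(r) else r)
    return float(np.mean(rs))


def ks2d_pvalue(D: float, n1: int, n2: int, r_corr: float = 0.0) -> float:
    """Asymptotic probability of exceeding D under the null."""
    if not 0 <= D <= 1:
        raise DomainError("D must lie in [0, 1]")
    if min(n1, n2) < 3:
        raise DomainError("samples too small")
    ne = n1 * n2 / (n1 + n2)
    sqne = np.sqrt(ne)
    denom = 1.0 + np.sqrt(max(0.0, 1.0 - r_corr ** 2)) * \
        (0.25 - 0.75 / sqne)
    p = float(special.kolmogorov(sqne * D / denom))
    return min(max(p, 0.0), 1.0)


def ks2d_test(s1, s2, method: str = "asymptotic",
              n_permutations: int = 999, seed: int = 0) -> KS2DResult:
    """Full test: D plus either the asymptotic or the permutation p."""
    pooled, in1, n1, n2 = _pooled(s1, s2)
    quadrants = _quadrant_matrices(pooled)
    D = _D_from_labels(quadrants, in1, n1, n2)
    r_corr = _pooled_correlation(s1, s2)
    if method == "asymptotic":
        p = ks2d_pvalue(D, n1, n2, r_corr)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        g = 0
        labels = in1.copy()
        for _ in range(n_permutations):
            rng.shuffle(labels)
            if _D_from_labels(quadrants, labels, n1, n2) >= D:
                g += 1
        p = (g + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KS2DResult(D=float(D), p=float(p), n1=n1, n2=n2, method=method,
                      r_corr=r_corr)


def bonferroni_gate(p_values, alpha: float = 0.05):
    """Reject flags at the Bonferroni-corrected level alpha / n_tests.

    Returns ``(flags, corrected_level)``; a p-value rejects when it is
    strictly below the corrected level.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    level = alpha / p.size
    return p < level, float(level)
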