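"""Fused inner loops of the surrogate exceedance scan.

The windowed Pearson coefficients for the observed pair and all
surrogate replicates are evaluated from shared cumulative-moment arrays.
Exceedance (|r_surr| >= |r_obs|) is tested on the cross-multiplied
squared form, which avoids a division and a square root per cell and is
exact for the comparison.  The W-scan kernel stops counting a cell's
exceedances as soon as the cell can no longer be significant, and stops
scanning widths at the first efficiency crossing.

When numba is unavailable the callers fall back to a vectorized numpy
implementation of the same logic.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_TOL = 1e-11


@njit(cache=False)
def moment_cumsums(xt, yt):
    """Cumulative sums (with leading zero) of x, y, x^2, y^2, x*y for a
    batch of demeaned series pairs.

    Inputs are time-major, shape (N, B); outputs are (N+1, B) so that
    the replicate loop of the scan kernels reads contiguous memory.
    """
    N, B = xt.shape
    Sx = np.zeros((N + 1, B))
    Sy = np.zeros((N + 1, B))
    Sxx = np.zeros((N + 1, B))
    Syy = np.zeros((N + 1, B))
    Sxy = np.zeros((N + 1, B))
    for j in range(N):
        for i in range(B):
            xv = xt[j, i]
            yv = yt[j, i]
            Sx[j + 1, i] = Sx[j, i] + xv
            Sy[j + 1, i] = Sy[j, i] + yv
            Sxx[j + 1, i] = Sxx[j, i] + xv * xv
            Syy[j + 1, i] = Syy[j, i] + yv * yv
            Sxy[j + 1, i] = Sxy[j, i] + xv * yv
    return Sx, Sy, Sxx, Syy, Sxy


@njit(cache=False)
def scan_observability(Sx, Sy, Sxx, Syy, Sxy, s, M, K, alpha, eta_threshold,
                       strict):
    """Width index (1-based) of the first efficiency crossing, or 0.

    Column 0 of the (N+1, B) moment arrays is the observed pair, columns
    1..R the surrogate replicates.
    """
    R = Sx.shape[1] - 1
    # largest exceedance count that still yields p < alpha
    g_max = int(np.floor(alpha * (R + 1) - 1.0 - 1e-9))
    if g_max < 0:
        return 0
    for m in range(1, M + 1):
        L = float(m * s)
        off = (M - m) * s // 2
        n_sig = 0
        for k in range(K):
            a = off + k * s
            b = a + m * s
            sx = Sx[b, 0] - Sx[a, 0]
            sy = Sy[b, 0] - Sy[a, 0]
            sxx = Sxx[b, 0] - Sxx[a, 0]
            syy = Syy[b, 0] - Syy[a, 0]
            vx = sxx - sx * sx / L
            vy = syy - sy * sy / L
            if vx <= _TOL * max(sxx, 1e-300) or \
                    vy <= _TOL * max(syy, 1e-300):
                continue  # undefined r: never significant
            cov = Sxy[b, 0] - Sxy[a, 0] - sx * sy / L
            num_obs = cov * cov
            den_obs = vx * vy
            g = 0
            for i in range(1, R + 1):
                sxi = Sx[b, i] - Sx[a, i]
                syi = Sy[b, i] - Sy[a, i]
                vxi = (Sxx[b, i] - Sxx[a, i]) - sxi * sxi / L
                vyi = (Syy[b, i] - Syy[a, i]) - syi * syi / L
                if vxi <= _TOL * max(Sxx[b, i] - Sxx[a, i], 1e-300) or \
                        vyi <= _TOL * max(Syy[b, i] - Syy[a, i], 1e-300):
                    continue
                ci = Sxy[b, i] - Sxy[a, i] - sxi * syi / L
                if ci * ci * den_obs >= num_obs * (vxi * vyi):
                    g += 1
                    if g > g_max:
                        break
            if g <= g_max:
                n_sig += 1
        eta = n_sig / K
        if eta > eta_threshold or (not strict and eta == eta_threshold):
            return m
    return 0


@njit(cache=False)
def exceedance_counts(Sx, Sy, Sxx, Syy, Sxy, s, M, K):
    """Full exceedance counts g(m, k) and validity mask of the observed
    r; no early termination (used for the complete p-value diagram)."""
    R = Sx.shape[1] - 1
    g = np.zeros((M, K), dtype=np.int64)
    ok = np.zeros((M, K), dtype=np.bool_)
    for m in range(1, M + 1):
        L = float(m * s)
        off = (M - m) * s // 2
        for k in range(K):
            a = off + k * s
            b = a + m * s
            sx = Sx[b, 0] - Sx[a, 0]
            sy = Sy[b, 0] - Sy[a, 0]
            sxx = Sxx[b, 0] - Sxx[a, 0]
            syy = Syy[b, 0] - Syy[a, 0]
            vx = sxx - sx * sx / L
            vy = syy - sy * sy / L
            if vx <= _TOL * max(sxx, 1e-300) or \
                    vy <= _TOL * max(syy, 1e-300):
                continue
            ok[m - 1, k] = True
            cov = Sxy[b, 0] - Sxy[a, 0] - sx * sy / L
            num_obs = cov * cov
            den_obs = vx * vy
            cnt = 0
            for i in range(1, R + 1):
                sxi = Sx[b, i] - Sx[a, i]
                syi = Sy[b, i] - Sy[a, i]
                vxi = (Sxx[b, i] - Sxx[a, i]) - sxi * sxi / L
                vyi = (Syy[b, i] - Syy[a, i]) - syi * syi / L
                if vxi <= _TOL * max(Sxx[b, i] - Sxx[a, i], 1e-300) or \
                        vyi <= _TOL * max(Syy[b, i] - Syy[a, i], 1e-300):
                    continue
                ci = Sxy[b, i] - Sxy[a, i] - sxi * syi / L
                if ci * ci * den_obs >= num_obs * (vxi * vyi):
                    cnt += 1
            g[m - 1, k] = cnt
    return g, ok
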