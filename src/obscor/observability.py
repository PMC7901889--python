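"""Time scale of observability of zero-delay cross-correlation.

The method probes a pair of simultaneous signals with moving windows of
widths ``m*w0`` (``m = 1..M``) sharing a common set of centers.  In each
window the sample Pearson coefficient ``r(k, w)`` is computed; its
significance is assessed against surrogate pairs that preserve the
amplitude spectrum (and optionally the amplitude distribution) of each
signal, yielding a p-value diagram ``p(k, w)``.  The efficiency
``eta(w)`` is the fraction of windows of width ``w`` that are significant
at the ``alpha`` threshold; the smallest width whose efficiency overcomes
0.5 is the time scale of observability ``W`` of the link.  Pairs whose
efficiency never overcomes the threshold carry no detectable link.

The per-window Pearson coefficients are evaluated from cumulative sums,
so a full diagram costs O(N + M*K) rather than O(M*K*window).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import _kernels
from .errors import SequenceTooShortError
from .io import NodeTable, TimeSeriesSet
from .params import MethodParams

__all__ = [
    "WindowGrid", "CorrelationDiagram", "PValueDiagram", "EfficiencyCurve",
    "LinkRecord", "build_window_grid", "windowed_pearson", "make_surrogate",
    "pvalue_diagram", "efficiency", "observability_timescale",
    "observability_from_pair", "assess_links", "links_to_frame",
]


# ---------------------------------------------------------------------------
# window grid


@dataclass(frozen=True)
class WindowGrid:
    """Multiscale set of window widths with shared centers.

    Widths are ``m*w0`` for ``m = 1..M``; centers start at ``M*w0/2`` and
    advance in steps of ``w0`` up to ``N*T - M*w0/2``, so every width uses
    the same centers and the widest window always fits.
    """

    w0: float
    M: int
    sampling_period: float
    n_samples: int
    w0_samples: int
    n_centers: int

    @property
    def widths(self) -> np.ndarray:
        return np.arange(1, self.M + 1) * self.w0

    @property
    def centers(self) -> np.ndarray:
        t0 = self.M * self.w0 / 2.0
        return t0 + np.arange(self.n_centers) * self.w0

    def window_bounds(self, m: int) -> tuple[int, int]:
        """(start offset of the first window, length in samples) for width
        index ``m`` (1-based).  Window k starts at offset + k*w0_samples."""
        s = self.w0_samples
        length = m * s
        offset = (self.M - m) * s // 2
        return offset, length

    def window_slice(self, m: int, k: int) -> slice:
        offset, length = self.window_bounds(m)
        start = offset + k * self.w0_samples
        return slice(start, start + length)


def build_window_grid(n_samples: int, sampling_period: float, w0: float,
                      M: int) -> WindowGrid:
    if sampling_period <= 0 or w0 <= 0:
        raise ValueError("sampling_period and w0 must be positive")
    s = w0 / sampling_period
    s_int = int(round(s))
    if s_int < 2 or abs(s - s_int) > 1e-6 * s:
        raise ValueError(
            f"w0={w0} must be a multiple (>= 2x) of the sampling period "
            f"{sampling_period}")
    if n_samples < M * s_int:
        raise SequenceTooShortError(
            f"sequence of {n_samples} samples is shorter than the largest "
            f"window M*w0 = {M * s_int} samples")
    n_centers = (n_samples - M * s_int) // s_int + 1
    return WindowGrid(w0=w0, M=M, sampling_period=sampling_period,
                      n_samples=n_samples, w0_samples=s_int,
                      n_centers=n_centers)


# ---------------------------------------------------------------------------
# windowed Pearson diagrams


@dataclass
class CorrelationDiagram:
    """r(k, w): rows = window centers, columns = widths; NaN where a
    window is constant in either series."""

    values: np.ndarray
    grid: WindowGrid


@dataclass
class PValueDiagram:
    """p(k, w) from the surrogate exceedance count, same shape as the
    correlation diagram; p >= 1/(n_surrogates + 1) everywhere defined."""

    values: np.ndarray
    grid: WindowGrid
    n_surrogates: int
    surrogate_method: str


@dataclass
class EfficiencyCurve:
    """eta(w): fraction of windows of width w that are significant."""

    eta: np.ndarray
    widths: np.ndarray
    alpha: float


@dataclass(frozen=True)
class LinkRecord:
    """One unordered node pair: distance, observability time scale (None
    when no link is detected) and hemisphere pairing (LL/LR/RR)."""

    node_a: str
    node_b: str
    d: float
    W: float | None
    hemisphere_pair: str


class _PairCumsums:
    """Cumulative first/second moments for a batch of series pairs.

    ``xs``/``ys`` have shape (B, N); window sums of x, y, x^2, y^2 and
    x*y over any sample interval come out as differences of cumsums.
    """

    def __init__(self, xs: np.ndarray, ys: np.ndarray):
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        # demeaning improves the conditioning of the variance differences
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        B, N = xs.shape
        self.n_samples = N

        def cs(v):
            out = np.zeros((B, N + 1))
            np.cumsum(v, axis=1, out=out[:, 1:])
            return out

        self.Sx = cs(xs)
        self.Sy = cs(ys)
        self.Sxx = cs(xs * xs)
        self.Syy = cs(ys * ys)
        self.Sxy = cs(xs * ys)

    def r(self, grid: WindowGrid, m: int) -> np.ndarray:
        """Pearson r for width index m at every center; shape (B, K)."""
        return self.r_block(grid, [m])[:, 0, :]

    def r_block(self, grid: WindowGrid, ms) -> np.ndarray:
        """Pearson r for several width indices at once; shape
        (B, len(ms), K).  One fancy-indexed gather per moment array."""
        ms = np.asarray(ms, dtype=int)
        if ms.min() < 1 or ms.max() > grid.M:
            raise ValueError(f"width indices outside 1..{grid.M}")
        if grid.n_samples != self.n_samples:
            raise ValueError("grid does not match the series length")
        s = grid.w0_samples
        K = grid.n_centers
        base = np.arange(K) * s
        offsets = np.array([grid.window_bounds(int(m))[0] for m in ms])
        lengths = ms * s
        lo = offsets[:, None] + base[None, :]          # (nm, K)
        hi = lo + lengths[:, None]
        L = lengths[None, :, None].astype(float)

        Sx = self.Sx[:, hi] - self.Sx[:, lo]           # (B, nm, K)
        Sy = self.Sy[:, hi] - self.Sy[:, lo]
        Sxx = self.Sxx[:, hi] - self.Sxx[:, lo]
        Syy = self.Syy[:, hi] - self.Syy[:, lo]
        Sxy = self.Sxy[:, hi] - self.Sxy[:, lo]
        vx = Sxx - Sx * Sx / L
        vy = Syy - Sy * Sy / L
        cov = Sxy - Sx * Sy / L
        # a window is 'constant' when its variance is at round-off level
        tol = 1e-11
        ok = (vx > tol * np.maximum(Sxx, 1e-300)) & \
             (vy > tol * np.maximum(Syy, 1e-300))
        r = np.full(cov.shape, np.nan)
        np.divide(cov, np.sqrt(vx * vy, where=ok, out=np.ones_like(vx)),
                  where=ok, out=r)
        np.clip(r, -1.0, 1.0, out=r)
        return r


def windowed_pearson(x: np.ndarray, y: np.ndarray,
                     grid: WindowGrid) -> CorrelationDiagram:
    """Sample Pearson coefficient over every (center, width) window."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) != grid.n_samples:
        raise ValueError("series length does not match the grid")
    cs = _PairCumsums(x[None, :], y[None, :])
    vals = np.empty((grid.n_centers, grid.M))
    for m in range(1, grid.M + 1):
        vals[:, m - 1] = cs.r(grid, m)[0]
    return CorrelationDiagram(values=vals, grid=grid)


# ---------------------------------------------------------------------------
# surrogates


def _ft_surrogates(x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogates: amplitude spectrum preserved exactly."""
    N = len(x)
    amp = np.abs(np.fft.rfft(x))
    nf = len(amp)
    # uniform phases as normalized complex Gaussians (cheaper than exp);
    # single precision suffices for random phases
    re = rng.standard_normal((n, nf), dtype=np.float32)
    im = rng.standard_normal((n, nf), dtype=np.float32)
    z = re + 1j * im
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    phasor = z / mag
    phasor[:, 0] = 1.0
    if N % 2 == 0:
        phasor[:, -1] = 1.0
    return np.fft.irfft(amp * phasor, n=N)


def _rank_remap(values: np.ndarray, sorted_target: np.ndarray) -> np.ndarray:
    """Reorder the sorted target values by the ranks of each row."""
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1, kind="stable")
    return sorted_target[ranks]


def _aaft_surrogates(x, n, rng):
    N = len(x)
    sorted_x = np.sort(x)
    ranks_x = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    gauss = np.sort(rng.standard_normal((n, N)), axis=1)[:, ranks_x]
    gs = np.empty_like(gauss)
    for i in range(n):
        gs[i] = _ft_surrogates(gauss[i], 1, rng)[0]
    return _rank_remap(gs, sorted_x)


def _iaaft_surrogates(x, n, rng, max_iter=100):
    N = len(x)
    amp = np.abs(np.fft.rfft(x))
    sorted_x = np.sort(x)
    # start from random permutations of the original values
    s = np.stack([rng.permutation(x) for _ in range(n)])
    prev = None
    for _ in range(max_iter):
        spec = np.fft.rfft(s, axis=1)
        mag = np.abs(spec)
        mag[mag == 0] = 1.0
        s = np.fft.irfft(spec / mag * amp, n=N, axis=1)
        s = _rank_remap(s, sorted_x)
        order = np.argsort(s, axis=1, kind="stable")
        if prev is not None and np.array_equal(order, prev):
            break
        prev = order
    return s


def _surrogate_batch(x, n, rng, method):
    if method == "ft":
        return _ft_surrogates(x, n, rng)
    if method == "aaft":
        return _aaft_surrogates(x, n, rng)
    if method == "iaaft":
        return _iaaft_surrogates(x, n, rng)
    raise ValueError(f"unknown surrogate method {method!r}")


def make_surrogate(x: np.ndarray, seed: int, method: str = "iaaft") -> np.ndarray:
    """One surrogate of ``x`` preserving its amplitude spectrum (``ft``)
    and, for ``aaft``/``iaaft``, its amplitude distribution."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need a 1-D series of length >= 4")
    rng = np.random.default_rng(seed)
    return _surrogate_batch(x, 1, rng, method)[0]


# ---------------------------------------------------------------------------
# p-value diagram, efficiency, W


def _count_exceedances(cs_obs, cs_surr_list, grid, ms):
    """g(m, k) = number of surrogate replicates with |r_surr| >= |r_obs|
    for each width index in ``ms``."""
    r_obs = cs_obs.r_block(grid, ms)[0]            # (nm, K)
    g = np.zeros(r_obs.shape, dtype=int)
    a_obs = np.abs(r_obs)
    for cs in cs_surr_list:
        rs = np.abs(cs.r_block(grid, ms))          # (B, nm, K)
        g += (rs >= a_obs[None]).sum(axis=0)       # NaN compares False
    return r_obs, g


_WIDTH_BLOCK = 8


def pvalue_diagram(x: np.ndarray, y: np.ndarray, grid: WindowGrid,
                   n_surrogates: int = 200, seed: int = 0,
                   method: str = "iaaft") -> PValueDiagram:
    """Surrogate-based p(k, w) with p = (g + 1)/(n_surrogates + 1).

    Both series are surrogated independently in every replicate and the
    full diagram is recomputed on the same grid; cells where the observed
    Pearson coefficient is undefined are left missing (NaN).
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ss = np.random.SeedSequence(seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))
    xs = _surrogate_batch(x, n_surrogates, rng_x, method)
    ys = _surrogate_batch(y, n_surrogates, rng_y, method)

    p = np.empty((grid.n_centers, grid.M))
    if _kernels.HAVE_NUMBA:
        moments = _stacked_moments(x, y, xs, ys)
        g, ok = _kernels.exceedance_counts(
            *moments, grid.w0_samples, grid.M, grid.n_centers)
        p[:] = ((g + 1) / (n_surrogates + 1)).T
        p[~ok.T] = np.nan
    else:
        cs_obs = _PairCumsums(x[None, :], y[None, :])
        # chunk the replicates to bound memory on long series
        chunk = max(1, int(3e7 // max(len(x), 1)))
        cs_surr = [
            _PairCumsums(xs[i:i + chunk], ys[i:i + chunk])
            for i in range(0, n_surrogates, chunk)
        ]
        for start in range(1, grid.M + 1, _WIDTH_BLOCK):
            ms = list(range(start, min(start + _WIDTH_BLOCK, grid.M + 1)))
            r_obs, g = _count_exceedances(cs_obs, cs_surr, grid, ms)
            block = (g + 1) / (n_surrogates + 1)
            block[~np.isfinite(r_obs)] = np.nan
            p[:, start - 1:start - 1 + len(ms)] = block.T
    return PValueDiagram(values=p, grid=grid, n_surrogates=n_surrogates,
                         surrogate_method=method)


def _stacked_moments(x, y, xs, ys):
    """Demeaned [observed; surrogates] stacks -> time-major moment
    cumsums for the scan kernels."""
    xa = np.vstack([x[None, :], xs])
    ya = np.vstack([y[None, :], ys])
    xa -= xa.mean(axis=1, keepdims=True)
    ya -= ya.mean(axis=1, keepdims=True)
    return _kernels.moment_cumsums(np.ascontiguousarray(xa.T),
                                   np.ascontiguousarray(ya.T))


def efficiency(p: PValueDiagram, alpha: float = 0.05) -> EfficiencyCurve:
    """Fraction of centers with p(k, w) < alpha, per width; missing cells
    count as non-significant."""
    vals = p.values
    with np.errstate(invalid="ignore"):
        sig = np.where(np.isfinite(vals), vals < alpha, False)
    return EfficiencyCurve(eta=sig.mean(axis=0), widths=p.grid.widths,
                           alpha=alpha)


def observability_timescale(curve: EfficiencyCurve, threshold: float = 0.5,
                            strict: bool = True) -> float | None:
    """Smallest width whose efficiency overcomes the threshold; None when
    no width qualifies (no link)."""
    above = curve.eta > threshold if strict else curve.eta >= threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    return float(curve.widths[idx[0]])


def observability_from_pair(x: np.ndarray, y: np.ndarray, grid: WindowGrid,
                            params: MethodParams,
                            seed=None) -> float | None:
    """W for one pair, scanning widths in increasing order and stopping at
    the first efficiency crossing.  Produces exactly the W of the full
    ``pvalue_diagram`` -> ``efficiency`` -> ``observability_timescale``
    chain run with the same seed (identical surrogates)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if seed is None:
        seed = params.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(2))
    R = params.n_surrogates
    xs = _surrogate_batch(x, R, rng_x, params.surrogate)
    ys = _surrogate_batch(y, R, rng_y, params.surrogate)
    if _kernels.HAVE_NUMBA:
        moments = _stacked_moments(x, y, xs, ys)
        m = _kernels.scan_observability(
            *moments, grid.w0_samples, grid.M, grid.n_centers,
            params.alpha, params.eta_threshold, params.strict_crossing)
        return float(m * grid.w0) if m else None
    cs_obs = _PairCumsums(x[None, :], y[None, :])
    chunk = max(1, int(3e7 // max(len(x), 1)))
    cs_surr = [_PairCumsums(xs[i:i + chunk], ys[i:i + chunk])
               for i in range(0, R, chunk)]
    thr = params.eta_threshold
    for start in range(1, grid.M + 1, _WIDTH_BLOCK):
        ms = list(range(start, min(start + _WIDTH_BLOCK, grid.M + 1)))
        r_obs, g = _count_exceedances(cs_obs, cs_surr, grid, ms)
        p = (g + 1) / (R + 1)
        sig = np.isfinite(r_obs) & (p < params.alpha)
        eta = sig.mean(axis=1)                     # per width in the block
        crossed = eta > thr if params.strict_crossing else eta >= thr
        idx = np.flatnonzero(crossed)
        if idx.size:
            return float((start + idx[0]) * grid.w0)
    return None


# ---------------------------------------------------------------------------
# link assessment over all pairs


def _pair_seed(master_seed: int, a: str, b: str) -> np.random.SeedSequence:
    """Order-independent, parallelism-safe per-pair stream."""
    lo, hi = sorted((a, b))
    digest = hashlib.sha256(f"{lo}|{hi}".encode()).digest()
    return np.random.SeedSequence((int(master_seed),
                                   int.from_bytes(digest[:8], "little")))


def hemisphere_pair(h1: str, h2: str) -> str:
    code = "".join(sorted(h[0].upper() for h in (h1, h2)))
    return code


def assess_links(ts: TimeSeriesSet, nodes: NodeTable,
                 params: MethodParams) -> list[LinkRecord]:
    """Assess every unordered node pair of a subject.

    Returns N(N-1)/2 records with Euclidean distance and (possibly
    absent) observability time scale, sorted by node ids.  Reproducible
    from the master seed: each pair draws from a stream derived from the
    sorted pair of node ids.
    """
    missing = set(ts.node_ids) - set(nodes.node_ids)
    if missing:
        raise ValueError(f"series nodes missing from node table: {sorted(missing)}")
    grid = build_window_grid(ts.n_samples, ts.sampling_period,
                             params.w0, params.M)
    records = []
    for na, nb in combinations(sorted(ts.node_ids), 2):
        d = float(np.linalg.norm(nodes.position(na) - nodes.position(nb)))
        W = observability_from_pair(ts.column(na), ts.column(nb), grid,
                                    params, seed=_pair_seed(params.seed, na, nb))
        records.append(LinkRecord(
            node_a=na, node_b=nb, d=d, W=W,
            hemisphere_pair=hemisphere_pair(nodes.hemisphere(na),
                                            nodes.hemisphere(nb))))
    return records


def links_to_frame(records: list[LinkRecord], subject_id: str) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame({
        "subject_id": subject_id,
        "node_a": [r.node_a for r in records],
        "node_b": [r.node_b for r in records],
        "hemisphere_pair": [r.hemisphere_pair for r in records],
        "d_mm": [r.d for r in records],
        "W_s": [np.nan if r.W is None else r.W for r in records],
    })
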