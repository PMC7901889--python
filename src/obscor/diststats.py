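"""Joint, marginal and conditional sample distributions of (d, W).

Distances may be binned linearly in mm or uniformly in ln d (natural
logarithm, d in mm).  The conditional mean curve ``Wbar`` per distance
bin is the probability-weighted sum of W bin centers under f(W | d); the
band reported alongside it is +-1 weighted standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDistributionError


def euclidean_distance(a, b) -> float:
    """L2 norm of the difference of two 3-D positions (mm)."""
    return float(np.linalg.norm(np.asarray(a, dtype=float) -
                                np.asarray(b, dtype=float)))


@dataclass(frozen=True)
class Binning2D:
    """Bin edges for the (d, W) plane; ``d_edges`` are in ln mm when
    ``log_d`` is set.  Bins are right-open except the last (closed)."""

    d_edges: np.ndarray
    W_edges: np.ndarray
    log_d: bool = False

    def __post_init__(self):
        object.__setattr__(self, "d_edges", np.asarray(self.d_edges, float))
        object.__setattr__(self, "W_edges", np.asarray(self.W_edges, float))
        for e in (self.d_edges, self.W_edges):
            if len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("edges must be strictly increasing, >= 2")

    @property
    def n_bins_d(self) -> int:
        return len(self.d_edges) - 1

    @property
    def n_bins_W(self) -> int:
        return len(self.W_edges) - 1

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def W_centers(self) -> np.ndarray:
        return 0.5 * (self.W_edges[:-1] + self.W_edges[1:])

    @classmethod
    def from_data(cls, d, W, n_bins_d: int = 25, n_bins_W: int = 25,
                  log_d: bool = False) -> "Binning2D":
        """Uniform bins spanning the min/max of the data on each axis."""
        d = np.asarray(d, float)
        W = np.asarray(W, float)
        if d.size == 0:
            raise EmptyDistributionError("no links to bin")
        x = np.log(d) if log_d else d
        d_edges = np.linspace(x.min(), x.max(), n_bins_d + 1)
        W_edges = np.linspace(W.min(), W.max(), n_bins_W + 1)
        # guard against a degenerate (single-valued) axis
        if d_edges[0] == d_edges[-1]:
            d_edges = d_edges + np.linspace(-0.5, 0.5, n_bins_d + 1)
        if W_edges[0] == W_edges[-1]:
            W_edges = W_edges + np.linspace(-0.5, 0.5, n_bins_W + 1)
        return cls(d_edges, W_edges, log_d)


@dataclass
class JointDistribution:
    """Normalized 2-D histogram f(d, W) over observable links."""

    f: np.ndarray       # (n_bins_d, n_bins_W), sums to 1
    counts: np.ndarray  # same shape, integer
    binning: Binning2D


@dataclass
class ConditionalCurve:
    """f(W | d) and its per-bin weighted mean/sd/count.

    ``x`` holds the distance-bin centers on the binned scale (ln mm when
    ``log_d``); bins with no links have NaN mean/sd and n = 0.
    """

    x: np.ndarray
    Wbar: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    f_W_given_d: np.ndarray
    log_d: bool

    @property
    def d(self) -> np.ndarray:
        """Distance-bin centers in mm."""
        return np.exp(self.x) if self.log_d else self.x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "d_mm": self.d, "Wbar_s": self.Wbar,
                             "sd_s": self.sd, "n": self.n})


def _observable(d, W):
    d = np.asarray(d, float)
    W = np.asarray(W, float)
    keep = np.isfinite(W) & np.isfinite(d)
    return d[keep], W[keep]


def joint_distribution(d, W, binning: Binning2D | None = None,
                       n_bins_d: int = 25, n_bins_W: int = 25,
                       log_d: bool = False) -> JointDistribution:
    """Normalized 2-D histogram of observable links.

    ``d``/``W`` are per-link arrays; entries with non-finite W (no link)
    are dropped.  When no binning is given, uniform bins spanning the
    data are built on the requested scale.
    """
    d, W = _observable(d, W)
    if d.size == 0:
        raise EmptyDistributionError("no observable links")
    if binning is None:
        binning = Binning2D.from_data(d, W, n_bins_d, n_bins_W, log_d)
    x = np.log(d) if binning.log_d else d
    counts, _, _ = np.histogram2d(x, W, bins=[binning.d_edges,
                                              binning.W_edges])
    counts = counts.astype(int)
    total = counts.sum()
    if total == 0:
        raise EmptyDistributionError("binning does not cover the data")
    return JointDistribution(f=counts / total, counts=counts, binning=binning)


def joint_from_links(links: pd.DataFrame, **kwargs) -> JointDistribution:
    """Convenience wrapper over a link table (columns d_mm, W_s)."""
    return joint_distribution(links["d_mm"].to_numpy(),
                              links["W_s"].to_numpy(), **kwargs)


def marginals(joint: JointDistribution) -> tuple[np.ndarray, np.ndarray]:
    """(g_d, g_W): the joint integrated along the W and d axes."""
    return joint.f.sum(axis=1), joint.f.sum(axis=0)


def conditional(joint: JointDistribution) -> ConditionalCurve:
    """Column-normalize f(d, W) by g_d and compute the weighted mean
    curve, its weighted standard deviation and the per-bin counts."""
    g_d = joint.f.sum(axis=1)
    cond = np.full_like(joint.f, np.nan)
    nz = g_d > 0
    cond[nz] = joint.f[nz] / g_d[nz, None]
    centers = joint.binning.W_centers
    Wbar = np.full(joint.binning.n_bins_d, np.nan)
    sd = np.full_like(Wbar, np.nan)
    Wbar[nz] = cond[nz] @ centers
    var = np.einsum("ij,ij->i", cond[nz],
                    (centers[None, :] - Wbar[nz, None]) ** 2)
    sd[nz] = np.sqrt(np.maximum(var, 0.0))
    return ConditionalCurve(x=joint.binning.d_centers, Wbar=Wbar, sd=sd,
                            n=joint.counts.sum(axis=1),
                            f_W_given_d=cond, log_d=joint.binning.log_d)


def conditional_raw(d, W, binning: Binning2D) -> ConditionalCurve:
    """Cross-check variant: per-distance-bin mean/sd of the raw W samples
    instead of the binned weighted sum."""
    d, W = _observable(d, W)
    x = np.log(d) if binning.log_d else d
    idx = np.digitize(x, binning.d_edges) - 1
    idx[x == binning.d_edges[-1]] = binning.n_bins_d - 1  # last bin closed
    nb = binning.n_bins_d
    Wbar = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for i in range(nb):
        sel = W[idx == i]
        n[i] = sel.size
        if sel.size:
            Wbar[i] = sel.mean()
            sd[i] = sel.std()
    return ConditionalCurve(x=binning.d_centers, Wbar=Wbar, sd=sd, n=n,
                            f_W_given_d=np.full((nb, binning.n_bins_W),
                                                np.nan),
                            log_d=binning.log_d)


def conditional_from_links(links: pd.DataFrame, n_bins_d: int = 50,
                           n_bins_W: int = 50,
                           log_d: bool = True) -> ConditionalCurve:
    """Link table -> joint -> conditional curve in one call (the usual
    50-bin, log-distance configuration)."""
    joint = joint_from_links(links, n_bins_d=n_bins_d, n_bins_W=n_bins_W,
                             log_d=log_d)
    return conditional(joint)


def plot_conditional(curve: ConditionalCurve, ax=None, fit=None):
    """Plot Wbar(x) with its 1-sigma band; optionally overlay a piecewise
    fit.  Requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = np.isfinite(curve.Wbar)
    ax.fill_between(curve.x[ok], (curve.Wbar - curve.sd)[ok],
                    (curve.Wbar + curve.sd)[ok], alpha=0.25,
                    label="±1σ")
    ax.plot(curve.x[ok], curve.Wbar[ok], "o-", ms=3, label="W̄")
    if fit is not None:
        xs = np.linspace(curve.x[ok].min(), curve.x[ok].max(), 200)
        ax.plot(xs, fit.predict(xs), "k-", lw=1, label="piecewise fit")
    ax.set_xlabel("ln d (mm)" if curve.log_d else "d (mm)")
    ax.set_ylabel("W̄ (s)")
    ax.legend()
    return ax
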