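"""Three-regime piecewise-linear fit of Wbar versus ln d.

The mean observability time scale depends linearly on ln d with three
distinct slopes m1, m2, m3 separated by breakpoints d12 < d23.  The fit
is a two-step procedure: three independent weighted least-squares lines
are fit on the ranges cut at user-supplied initial breakpoints; the two
intersection abscissae replace the breakpoints; the lines are refit once
on the updated ranges.  Segment continuity is deliberately not enforced
— the three lines are independent and only their intersections define
the regime boundaries.

A power-law comparison fit W = W0 (d/d0)^gamma is provided for the third
regime (linear fit of ln W on ln(d/d0)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .diststats import ConditionalCurve
from .errors import DegenerateFitError, FitFailureError

DEFAULT_INIT_D12 = 44.0
DEFAULT_INIT_D23 = 68.0


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    cov: np.ndarray       # 2x2 covariance of (slope, intercept)
    rss: float
    n: int

    @property
    def slope_err(self) -> float:
        return float(np.sqrt(max(self.cov[0, 0], 0.0)))

    @property
    def intercept_err(self) -> float:
        return float(np.sqrt(max(self.cov[1, 1], 0.0)))

    def __call__(self, x):
        return self.slope * np.asarray(x) + self.intercept


def fit_line(x, y, weights=None) -> LineFit:
    """Weighted least-squares straight line with parameter covariance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateFitError("need at least 2 distinct abscissae")
    X = sm.add_constant(x)  # columns: const, x
    if weights is None:
        res = sm.OLS(y, X).fit()
    else:
        res = sm.WLS(y, X, weights=np.asarray(weights, float)).fit()
    # reorder to (slope, intercept)
    cov = np.asarray(res.cov_params())[[1, 0]][:, [1, 0]]
    cov = np.nan_to_num(cov, nan=0.0)
    return LineFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                   cov=cov, rss=float(res.ssr), n=int(x.size))


def intersect_lines(l1: LineFit, l2: LineFit) -> tuple[float, float]:
    """Abscissa of intersection with first-order-propagated uncertainty."""
    dm = l1.slope - l2.slope
    scale = max(abs(l1.slope), abs(l2.slope), 1e-30)
    if abs(dm) < 1e-12 * scale:
        raise FitFailureError("lines are parallel; no intersection")
    db = l2.intercept - l1.intercept
    x_star = db / dm
    # gradients of x* wrt (slope, intercept) of each line
    g1 = np.array([-x_star / dm, -1.0 / dm])
    g2 = np.array([x_star / dm, 1.0 / dm])
    var = float(g1 @ l1.cov @ g1 + g2 @ l2.cov @ g2)
    return float(x_star), float(np.sqrt(max(var, 0.0)))


@dataclass
class PiecewiseFit:
    """Result of the two-step three-line fit (abscissa is ln d, mm)."""

    slopes: np.ndarray          # (m1, m2, m3), s per unit ln d
    slope_errs: np.ndarray
    intercepts: np.ndarray
    intercept_errs: np.ndarray
    d12: float                  # mm
    d23: float
    d12_err: float
    d23_err: float
    lines: tuple[LineFit, LineFit, LineFit]
    segment_n: np.ndarray
    segment_rss: np.ndarray
    history: list = field(default_factory=list)

    def predict(self, x):
        """Piecewise prediction at ln-distance ``x`` (may be
        discontinuous at the breakpoints)."""
        x = np.asarray(x, float)
        b1, b2 = np.log(self.d12), np.log(self.d23)
        seg = np.where(x <= b1, 0, np.where(x <= b2, 1, 2))
        out = np.empty_like(x, dtype=float)
        for i, line in enumerate(self.lines):
            out[seg == i] = line(x[seg == i])
        return out


def _segment_masks(x, ln12, ln23):
    return (x <= ln12), (x > ln12) & (x <= ln23), (x > ln23)


def _fit_three(x, y, w, ln12, ln23, min_points):
    lines = []
    for i, mask in enumerate(_segment_masks(x, ln12, ln23)):
        if mask.sum() < min_points:
            raise FitFailureError(
                f"segment {i + 1} has {int(mask.sum())} usable bins "
                f"(< {min_points}) for breakpoints "
                f"({np.exp(ln12):.3g}, {np.exp(ln23):.3g}) mm")
        lines.append(fit_line(x[mask], y[mask],
                              None if w is None else w[mask]))
    return tuple(lines)


def _curve_inputs(curve):
    if isinstance(curve, ConditionalCurve):
        x = curve.x if curve.log_d else np.log(curve.x)
        return x, curve.Wbar, curve.sd, curve.n
    raise TypeError("expected a ConditionalCurve or explicit arrays")


def two_step_piecewise_fit(curve=None, init_d12: float = DEFAULT_INIT_D12,
                           init_d23: float = DEFAULT_INIT_D23, *,
                           x=None, y=None, sd=None, n=None,
                           iterate: bool = False, max_iter: int = 50,
                           min_points: int = 3) -> PiecewiseFit:
    """Two-step three-regime fit of the conditional mean curve.

    Accepts either a :class:`ConditionalCurve` (whose distance axis is
    taken to ln mm) or explicit arrays ``x`` (ln d), ``y`` (Wbar) with
    optional per-bin ``sd`` and ``n``.  Weights default to ``n / sd**2``
    when both are available and positive, otherwise the fit is
    unweighted.  Empty and singleton bins are excluded.  Exactly two
    steps are performed unless ``iterate`` is set, in which case the
    intersection update is repeated to convergence.
    """
    if curve is not None:
        x, y, sd, n = _curve_inputs(curve)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    if n is not None:
        n = np.asarray(n, float)
        keep &= n >= 2  # singleton bins carry no dispersion information
    w = None
    if sd is not None and n is not None:
        sd = np.asarray(sd, float)
        pos = sd[keep & np.isfinite(sd) & (sd > 0)]
        if pos.size:
            # zero-dispersion bins get the smallest observed sd instead of
            # an infinite weight
            sd_eff = np.where(np.isfinite(sd) & (sd > 0), sd, pos.min())
            w = n / sd_eff ** 2
    x, y = x[keep], y[keep]
    if w is not None:
        w = w[keep]
    if not 0 < init_d12 < init_d23:
        raise ValueError("initial breakpoints must satisfy 0 < d12 < d23")

    history = []
    ln12, ln23 = np.log(init_d12), np.log(init_d23)
    lines = _fit_three(x, y, w, ln12, ln23, min_points)
    n_steps = max_iter if iterate else 2
    for step in range(n_steps):
        x12, s12 = intersect_lines(lines[0], lines[1])
        x23, s23 = intersect_lines(lines[1], lines[2])
        history.append({"step": step + 1, "d12": float(np.exp(x12)),
                        "d23": float(np.exp(x23)),
                        "slopes": [ln.slope for ln in lines]})
        if not x12 < x23:
            raise FitFailureError(
                f"updated breakpoints not ordered: d12={np.exp(x12):.3g} "
                f">= d23={np.exp(x23):.3g} mm; history={history}")
        if not (x.min() < x12 and x23 < x.max()):
            raise FitFailureError(
                f"updated breakpoints ({np.exp(x12):.3g}, "
                f"{np.exp(x23):.3g}) mm fall outside the data range; "
                f"history={history}")
        converged = step > 0 and abs(x12 - ln12) < 1e-10 and \
            abs(x23 - ln23) < 1e-10
        ln12, ln23 = x12, x23
        if step < n_steps - 1:
            lines = _fit_three(x, y, w, ln12, ln23, min_points=2)
        if iterate and converged:
            break
    masks = _segment_masks(x, ln12, ln23)
    return PiecewiseFit(
        slopes=np.array([ln.slope for ln in lines]),
        slope_errs=np.array([ln.slope_err for ln in lines]),
        intercepts=np.array([ln.intercept for ln in lines]),
        intercept_errs=np.array([ln.intercept_err for ln in lines]),
        d12=float(np.exp(ln12)), d23=float(np.exp(ln23)),
        d12_err=float(np.exp(ln12) * s12), d23_err=float(np.exp(ln23) * s23),
        lines=lines,
        segment_n=np.array([int(m.sum()) for m in masks]),
        segment_rss=np.array([ln.rss for ln in lines]),
        history=history)


def bootstrap_breakpoints(x, y, sd=None, n=None,
                          init_d12: float = DEFAULT_INIT_D12,
                          init_d23: float = DEFAULT_INIT_D23,
                          n_boot: int = 200, seed: int = 0) -> dict:
    """Bootstrap-over-bins cross-check of the breakpoint uncertainties."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    d12s, d23s = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        try:
            fit = two_step_piecewise_fit(
                x=x[idx], y=np.asarray(y)[idx],
                sd=None if sd is None else np.asarray(sd)[idx],
                n=None if n is None else np.asarray(n)[idx],
                init_d12=init_d12, init_d23=init_d23)
        except (FitFailureError, DegenerateFitError):
            continue
        d12s.append(fit.d12)
        d23s.append(fit.d23)
    return {"d12_sd": float(np.std(d12s)) if d12s else np.nan,
            "d23_sd": float(np.std(d23s)) if d23s else np.nan,
            "n_success": len(d12s)}


@dataclass(frozen=True)
class PowerLawFit:
    """W = W0 (d/d0)^gamma fitted on the third regime."""

    gamma: float
    gamma_err: float
    W0: float
    W0_err: float
    d0: float


def fit_power_law(d, W, d0: float = 75.0, weights=None) -> PowerLawFit:
    """Linear fit of ln W on ln(d/d0): slope = gamma, exp(intercept) = W0."""
    d = np.asarray(d, float)
    W = np.asarray(W, float)
    keep = np.isfinite(d) & np.isfinite(W)
    d, W = d[keep], W[keep]
    if weights is not None:
        weights = np.asarray(weights, float)[keep]
    if d.size < 3:
        raise DegenerateFitError("need at least 3 points for the power law")
    if np.any(d <= 0) or np.any(W <= 0) or d0 <= 0:
        raise ValueError("d, W and d0 must be positive")
    line = fit_line(np.log(d / d0), np.log(W), weights)
    W0 = float(np.exp(line.intercept))
    return PowerLawFit(gamma=line.slope, gamma_err=line.slope_err,
                       W0=W0, W0_err=W0 * line.intercept_err, d0=d0)
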