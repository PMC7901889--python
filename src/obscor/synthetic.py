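"""Synthetic cohorts with a known W(ln d) ground truth.

Node geometries are drawn inside two mirrored half-ellipsoids of
realistic head scale; every subject's signals are Gaussian band-limited
noises mixed so that each pair's expected zero-lag correlation equals
the calibration inverse of the target piecewise-linear W(ln d), with a
configurable fraction of pairs left uncorrelated.  Only the correlation
structure that the analysis assumes is emulated — no neural spectra,
forward models or artifacts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .errors import DomainError, GenerationError, GeometryError
from .io import NodeTable, TimeSeriesSet
from .observability import build_window_grid, observability_from_pair
from .params import MethodParams

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# ground truth and configuration


@dataclass(frozen=True)
class GroundTruth:
    """Target piecewise-linear relationship between W and ln d.

    ``intercept`` is W at the first breakpoint ``d12``; slopes are in
    seconds per unit ln(d/mm); ``w_range`` clips the implied targets.
    """

    slopes: tuple[float, float, float] = (7.0, 19.1, 6.7)
    breakpoints: tuple[float, float] = (44.0, 68.3)
    intercept: float = 11.9
    unlinked_fraction: float = 0.6
    w_range: tuple[float, float] = (0.6, 29.0)

    def __post_init__(self):
        if not self.breakpoints[0] < self.breakpoints[1]:
            raise ValueError("breakpoints must be increasing")
        if not 0 <= self.unlinked_fraction <= 1:
            raise ValueError("unlinked_fraction must lie in [0, 1]")
        if not self.w_range[0] < self.w_range[1]:
            raise ValueError("w_range must be increasing")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort geometry and signal parameters.

    Defaults mirror typical source-level resting-state recordings: 72
    nodes over two hemispheres,
    250 Hz sampling, 180 s per subject, 0.5-45 Hz band.  ``duration``
    must be at least five times the maximum probed time scale.
    """

    n_nodes: int = 72
    n_subjects: int = 10
    sampling_period: float = 0.004
    duration: float = 180.0
    noise_band: tuple[float, float] = (0.5, 45.0)
    seed: int = 0
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    position_jitter_mm: float = 2.0
    max_probed_scale: float = 30.0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.duration < 5 * self.max_probed_scale:
            raise ValueError(
                "duration must be at least 5x the maximum probed time scale")
        nyq = 0.5 / self.sampling_period
        if self.noise_band is not None and self.noise_band[1] > nyq + 1e-9:
            raise ValueError("noise band exceeds the Nyquist frequency")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.sampling_period))

    @classmethod
    def reduced_desk(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Desk-scale preset: 25 Hz sampling, 0.5-10 Hz band, 160 s (the
        standard minimum analyzed duration), matching the reduced method preset
        (:meth:`MethodParams.reduced`)."""
        cfg = cls(sampling_period=0.04, duration=160.0,
                  noise_band=(0.5, 10.0), seed=seed)
        return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# geometry


_SEMI_AXES = (70.0, 85.0, 65.0)  # lateral, anterior-posterior, vertical, mm


def _atlas_labels() -> pd.DataFrame:
    path = importlib.resources.files("obscor.data") / "atlas_areas.tsv"
    return pd.read_csv(path, sep="\t")


def place_nodes(n_nodes: int, seed: int, min_distance: float = 10.0,
                semi_axes: tuple[float, float, float] = _SEMI_AXES,
                midline_margin: float = 3.0) -> NodeTable:
    """Rejection-sample node positions inside two mirrored half-ellipsoid
    hemispheres so that all pairwise distances exceed ``min_distance``.

    Nodes alternate between hemispheres; labels are drawn from the
    bundled atlas-area table where available.  Deterministic given the
    seed; raises :class:`GeometryError` when the spacing constraint
    cannot be met within a bounded number of attempts.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    ax = np.asarray(semi_axes, float)
    positions = np.empty((n_nodes, 3))
    hemis = []
    max_attempts = 2000 * n_nodes
    attempts = 0
    i = 0
    while i < n_nodes:
        if attempts >= max_attempts:
            raise GeometryError(
                f"could not place {n_nodes} nodes with pairwise distance "
                f"> {min_distance} mm after {max_attempts} attempts")
        attempts += 1
        # uniform point in the ellipsoid via a scaled unit ball
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        p = ax * u * rng.uniform() ** (1.0 / 3.0)
        if abs(p[0]) < midline_margin:
            continue
        hemi = "left" if i % 2 == 0 else "right"
        p[0] = -abs(p[0]) if hemi == "left" else abs(p[0])
        if i > 0:
            dist = np.linalg.norm(positions[:i] - p, axis=1)
            if dist.min() <= min_distance:
                continue
        positions[i] = p
        hemis.append(hemi)
        i += 1

    atlas = _atlas_labels()
    pools = {h: list(atlas.loc[atlas["hemisphere"] == h, "label"])
             for h in ("left", "right")}
    labels = []
    for k, h in enumerate(hemis):
        labels.append(str(pools[h].pop(0)) if pools[h] else f"area{k + 1}")
    ids = [f"{h[0].upper()}{k + 1:03d}" for k, h in enumerate(hemis)]
    return NodeTable(ids, labels, hemis, positions)


# ---------------------------------------------------------------------------
# target W and the rho <-> W calibration


def target_W(d, gt: GroundTruth):
    """Continuous piecewise-linear target W(ln d), clipped to w_range."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise DomainError("distances must be positive")
    m1, m2, m3 = gt.slopes
    b1, b2 = np.log(gt.breakpoints[0]), np.log(gt.breakpoints[1])
    x = np.log(d_arr)
    w = np.where(
        x <= b1, gt.intercept + m1 * (x - b1),
        np.where(x <= b2, gt.intercept + m2 * (x - b1),
                 gt.intercept + m2 * (b2 - b1) + m3 * (x - b2)))
    w = np.clip(w, gt.w_range[0], gt.w_range[1])
    return float(w) if np.isscalar(d) else w


@dataclass
class CalibrationCurve:
    """Monotone mapping between generating correlation and typical W.

    ``statistic`` records which location statistic of the estimated W
    the curve tracks (``median`` over all replicates with censored
    estimates as +inf, or ``mean`` over the finite ones — the quantity
    the conditional-mean curve measures).
    """

    rho_grid: np.ndarray
    W_of_rho: np.ndarray  # non-increasing in rho
    n_reps: int
    seed: int
    statistic: str = "median"

    def rho_for_W(self, W):
        """Inverse lookup: correlation needed to produce a target W.

        Interpolates in log-log space, where the relationship is close
        to linear (W ~ rho^-2 at small rho); clips to the grid ends.
        """
        # strictly increasing W support for interpolation
        logw = np.log(self.W_of_rho[::-1])
        logr = np.log(self.rho_grid[::-1])
        keep = np.concatenate([[True], np.diff(logw) > 0])
        logw, logr = logw[keep], logr[keep]
        out = np.interp(np.log(np.asarray(W, float)), logw, logr,
                        left=logr[0], right=logr[-1])
        return np.exp(out)


def effective_sampling_period(sampling_period: float,
                              noise_band: tuple[float, float] | None) -> float:
    """Decorrelation interval of band-limited noise: the larger of the
    sampling period and 1/(2 * bandwidth)."""
    if noise_band is None:
        return sampling_period
    bw = noise_band[1] - noise_band[0]
    return max(sampling_period, 1.0 / (2.0 * bw))


def fisher_z_W(rho, t_eff: float):
    """Fisher-z power heuristic: samples needed to detect a correlation
    rho at the 5% level, converted to a time scale."""
    rho = np.asarray(rho, float)
    n_star = (_Z975 / np.arctanh(rho)) ** 2 + 3.0
    return n_star * t_eff


def analytic_calibration(config: SyntheticConfig,
                         n_grid: int = 60) -> CalibrationCurve:
    """Closed-form initializer of the rho -> W curve (no simulation)."""
    rho = np.linspace(0.01, 0.995, n_grid)
    t_eff = effective_sampling_period(config.sampling_period,
                                      config.noise_band)
    return CalibrationCurve(rho_grid=rho, W_of_rho=fisher_z_W(rho, t_eff),
                            n_reps=0, seed=config.seed)


def _band_limited_noise(rng, n_series, n_samples, sampling_period, band):
    """Unit-variance Gaussian noise, brick-wall filtered to ``band``."""
    z = rng.standard_normal((n_series, n_samples))
    if band is None:
        return z
    freqs = np.fft.rfftfreq(n_samples, d=sampling_period)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise GenerationError("noise band contains no FFT bins")
    spec = np.fft.rfft(z, axis=1)
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def calibrate_rho_to_W(config: SyntheticConfig, method: MethodParams,
                       rho_grid=None, n_reps: int = 30,
                       statistic: str = "median") -> CalibrationCurve:
    """Monte-Carlo calibration of the rho -> W mapping.

    For each rho on the grid, simulates ``x = sqrt(rho) z + sqrt(1-rho)
    e1`` / ``y = sqrt(rho) z + sqrt(1-rho) e2`` pairs of band-limited
    noises, runs the full W estimator and records a location statistic
    of the estimates: the ``median`` (censored estimates counted as
    infinite) or the ``mean`` over the finite estimates only, which is
    the quantity the conditional-mean curve of the analysis measures.
    A grid point with no usable estimates falls back to the Fisher-z
    heuristic.  The curve is made non-increasing by isotonic regression
    (weighted by the number of usable estimates).
    """
    if n_reps < 20:
        raise ValueError("n_reps must be at least 20")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    if rho_grid is None:
        # the mapping is steepest (and most often censored) at small rho;
        # sample that region densely
        rho_grid = np.concatenate([np.geomspace(0.05, 0.16, 10),
                                   np.geomspace(0.19, 0.9, 8)])
    rho_grid = np.asarray(rho_grid, float)
    if np.any((rho_grid <= 0) | (rho_grid >= 1)):
        raise DomainError("rho grid must lie strictly inside (0, 1)")
    rho_grid = np.sort(rho_grid)

    N = config.n_samples
    grid = build_window_grid(N, config.sampling_period, method.w0, method.M)
    t_eff = effective_sampling_period(config.sampling_period,
                                      config.noise_band)
    w_loc = np.empty(len(rho_grid))
    weights = np.ones(len(rho_grid))
    for i, rho in enumerate(rho_grid):
        ws = []
        # censoring thins the usable estimates at small rho; compensate
        reps_here = 2 * n_reps if rho < 0.15 else n_reps
        for rep in range(reps_here):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(config.seed), 0xCA11B, i, rep)))
            z, e1, e2 = _band_limited_noise(rng, 3, N,
                                            config.sampling_period,
                                            config.noise_band)
            x = np.sqrt(rho) * z + np.sqrt(1 - rho) * e1
            y = np.sqrt(rho) * z + np.sqrt(1 - rho) * e2
            W = observability_from_pair(
                x, y, grid, method,
                seed=np.random.SeedSequence(
                    (int(config.seed), 0xCA11B, i, rep, 1)))
            ws.append(np.inf if W is None else W)
        ws = np.asarray(ws)
        finite = np.isfinite(ws)
        if statistic == "median":
            loc = float(np.median(ws))
            weights[i] = max(int(finite.sum()), 1)
        else:
            loc = float(ws[finite].mean()) if finite.any() else np.inf
            weights[i] = max(int(finite.sum()), 1)
        w_loc[i] = loc if np.isfinite(loc) else fisher_z_W(rho, t_eff)

    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    w_mono = iso.fit_transform(rho_grid, w_loc, sample_weight=weights)
    return CalibrationCurve(rho_grid=rho_grid, W_of_rho=np.asarray(w_mono),
                            n_reps=n_reps, seed=config.seed,
                            statistic=statistic)


# ---------------------------------------------------------------------------
# cohort generation


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Factor L with L L^T ~= C, rows normalized so diag(L L^T) = 1."""
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, 1e-10, None)
    L = vecs * np.sqrt(vals)
    norms = np.linalg.norm(L, axis=1, keepdims=True)
    if np.any(norms == 0) or not np.all(np.isfinite(L)):
        raise GenerationError("correlation factorization failed")
    return L / norms


def generate_cohort(config: SyntheticConfig,
                    method: MethodParams | None = None,
                    calibration: CalibrationCurve | None = None,
                    ) -> tuple[NodeTable, list[TimeSeriesSet], GroundTruth]:
    """Generate a cohort of correlated series with known ground truth.

    Per subject, node positions are jittered (anatomical variability),
    pairwise target correlations are looked up from the calibration
    inverse of ``target_W``, a random ``unlinked_fraction`` of pairs is
    zeroed, and the resulting target matrix is repaired to the nearest
    correlation matrix before being factored onto independent
    band-limited noises.  Bit-deterministic given the config seed.

    The returned node table holds the shared atlas positions; each
    subject's series carries its own jittered geometry (``ts.nodes``),
    mirroring the per-subject anatomical distances a real analysis
    measures.
    """
    gt = config.ground_truth
    if calibration is None:
        calibration = analytic_calibration(config)
    nodes = place_nodes(config.n_nodes,
                        seed=np.random.SeedSequence((int(config.seed), 0)))
    n = config.n_nodes
    N = config.n_samples
    iu = np.triu_indices(n, k=1)
    subjects = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(config.seed), 1, s)))
        jitter = rng.normal(0.0, config.position_jitter_mm, size=(n, 3))
        pos = nodes.positions + jitter
        diff = pos[:, None, :] - pos[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(axis=2))
        rho = calibration.rho_for_W(target_W(dmat[iu], gt))
        n_pairs = len(rho)
        n_unlinked = int(round(gt.unlinked_fraction * n_pairs))
        unlinked = rng.choice(n_pairs, size=n_unlinked, replace=False)
        rho[unlinked] = 0.0
        C = np.eye(n)
        C[iu] = rho
        C[(iu[1], iu[0])] = rho
        try:
            if np.linalg.eigvalsh(C).min() < -1e-10:
                import warnings

                with warnings.catch_warnings():
                    # residual negative eigenvalues are clipped below
                    warnings.simplefilter("ignore")
                    C = np.asarray(corr_nearest(C, threshold=1e-12,
                                                n_fact=100))
            L = _psd_factor(C)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise GenerationError(
                f"correlation repair failed for subject {s}: {exc}") from exc
        Z = _band_limited_noise(rng, n, N, config.sampling_period,
                                config.noise_band)
        samples = (L @ Z).T
        subject_nodes = NodeTable(list(nodes.node_ids), list(nodes.labels),
                                  list(nodes.hemispheres), pos)
        subjects.append(TimeSeriesSet(
            subject_id=f"S{s + 1:03d}",
            sampling_period=config.sampling_period,
            node_ids=list(nodes.node_ids), samples=samples,
            nodes=subject_nodes))
    return nodes, subjects, gt


def draw_ages(n_subjects: int, seed: int,
              age_range: tuple[int, int] = (18, 88)) -> np.ndarray:
    """Uniform integer ages over the cohort's range (18-88 years)."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA6E)))
    return rng.integers(age_range[0], age_range[1] + 1, size=n_subjects)
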