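# Methods

## The estimator: time scale of observability

Two simultaneously sampled signals (length `N`, sampling period `T`) are
probed with moving windows of widths `m·w0`, `m = 1..M`.  All widths
share one set of center points: the first center sits at `M·w0/2`,
successive centers advance by `w0`, and the last center is at
`N·T − M·w0/2`, so the widest window always fits and every width uses
the same number of windows.  In each window the sample Pearson
coefficient `r(k, w)` is computed (zero-delay — no lag is scanned).

Significance is assessed against surrogate data: in each of
`n_surrogates` replicates *both* full-length series are replaced by
surrogates, the full diagram is recomputed on the same grid, and the
cell's p-value is `(g + 1) / (n_surrogates + 1)` where `g` counts
replicates with `|r_surr| ≥ |r|` (two-sided; the estimator never
returns 0, and its floor is `1/(n_surrogates+1)`).  Surrogates are
full-length, not per-window, so the null preserves each signal's
within-window autocorrelation.  Three surrogate constructions are
provided: `ft` (phase randomization; preserves the amplitude spectrum
exactly), `aaft`, and `iaaft` (amplitude-adjusted variants that also
preserve the marginal distribution; `iaaft` is the default).

The efficiency `η(w)` is the fraction of windows of width `w` with
`p < α` (default `α = 0.05`); cells whose Pearson coefficient is
undefined (constant window) count as non-significant.  A link exists
when `η(w)` strictly exceeds the efficiency threshold 0.5 for some
width; the smallest such width is the time scale of observability `W`.
`W` is therefore quantized to multiples of `w0` and bounded by `M·w0`;
pairs that never cross the threshold carry no link (`W` absent).  Ties
at exactly 0.5 do not qualify (switchable via `strict_crossing`).

The default operating point is `w0 = 0.2 s`, `M = 150` (widths
0.2–30 s; 50 samples per minimum window at 4 ms sampling), 200
surrogates, `α = 0.05`, threshold 0.5.

Implementation note: all windowed moments are taken from cumulative
sums, and the surrogate exceedance scan runs as a fused kernel (numba
when available, vectorized numpy otherwise) that stops counting a
cell's exceedances once the cell can no longer be significant and stops
scanning widths at the first efficiency crossing.  The fast scan is
exactly equivalent to the full diagram chain run with the same seed;
tests assert this equality.  Per-pair random streams are derived from a
hash of the sorted node-id pair and the master seed, so results are
independent of node ordering and safe to parallelize.

## Epoch standardization

Artifact-free epochs are reduced to standard analyzed durations: a
longest epoch of at least 240 s is trimmed symmetrically to 240 s
(equal sample counts removed at both ends, the odd leftover sample from
the end); between 180 and 240 s, to 180 s; below 180 s the two longest
epochs together supply 180 s — the longest is kept whole and the
second-longest trimmed symmetrically to the remainder — or 160 s when
180 s is unreachable; below a combined 160 s the subject is excluded.
The split rule for the two-epoch case is one reading of an
underspecified procedure and is documented as such.

## Distance statistics

Distances are Euclidean, in mm, between node positions; the natural
logarithm is used wherever distance is logged.  The joint distribution
`f(d, W)` is a normalized 2-D histogram over observable links (default
25 or 50 bins per axis, uniform on the chosen scale, right-open bins
with the last bin closed).  Marginals are axis sums.  The conditional
`f(W | d) = f(d, W)/g_d(d)` is column-normalized; the conditional mean
curve `W̄` is the probability-weighted sum of W bin centers per
distance bin, with a weighted standard deviation and the per-bin count.
A raw-sample per-bin mean is provided as a cross-check variant.

## Three-regime fit

`W̄` versus `ln d` is fit with three independent straight lines
(weighted least squares, weights `n/sd²` per bin; empty and singleton
bins excluded; zero-dispersion bins get the smallest observed sd rather
than infinite weight).  The two-step procedure: cut at user-supplied
initial breakpoints (defaults 44 and 68 mm), fit three lines, replace
the breakpoints by the two intersection abscissae, refit once.  Exactly
two steps are performed by default; an iterate-to-convergence mode
exists but is off.  Final breakpoints are the step-2 intersections;
their uncertainties come from first-order propagation through
`x* = (b2 − b1)/(m1 − m2)` using the fit covariances, with a
bootstrap-over-bins cross-check.  Segment continuity is *not* enforced;
only the intersections define the regime boundaries.

A caveat verified numerically: with exactly two steps, initials far
from the true breakpoints leave a small (~1%) residual in the middle
slope from points caught between the estimated and true kinks; the
default initials or the iterate mode remove it.

The third-regime comparison fit is `W = W0 (d/d0)^γ` with `d0 = 75 mm`,
obtained as a straight line of `ln W` on `ln(d/d0)`.

## Two-dimensional KS control

The two-sample Fasano–Franceschini statistic: every data point of each
sample serves as a quadrant origin; `D` is the mean of the two
per-sample maxima of the absolute difference between the samples'
quadrant fractions.  Quadrants are open — points on a dividing line
(including the origin) are excluded from all four counts while the
denominators keep the full sample sizes; this tie convention is one of
several in the literature and is fixed here for reproducibility.  The
asymptotic p-value uses the effective size `n1·n2/(n1+n2)` and the
`√(1−r²)` correlation correction (r is the mean of the two samples'
coordinate correlations) inside the Kolmogorov tail function; a
label-permutation mode (`p = (g+1)/(B+1)`) is the resampling reference
and the mode used for the node-set control, with a Bonferroni gate at
`0.05 / n_subjects`.

## Synthetic cohorts

The generator emulates just enough structure to exercise every stage:

* **Geometry.** Nodes are rejection-sampled inside two mirrored
  half-ellipsoids of head scale (semi-axes 70/85/65 mm, 3 mm midline
  margin), alternating hemispheres, with all pairwise distances above
  10 mm; labels come from a bundled 72-area atlas table.  Pair
  distances span roughly 10–175 mm.
* **Ground truth.** `W(ln d)` is continuous piecewise-linear with
  slopes (7.0, 19.1, 6.7) s per unit ln d and breakpoints (44, 68.3)
  mm; the intercept `W(44 mm) = 11.9 s` places targets within
  ~(1.5, 26.6) s for the generated geometries, inside the probed
  0.2–30 s band; a clip band (0.6, 29 s) guards the edges.  A fraction
  0.6 of pairs carries no shared signal at all.
* **Signals.** Gaussian band-limited noises (brick-wall filter,
  default 0.5–45 Hz at 250 Hz) mixed through a factor of the target
  pairwise correlation matrix; the matrix is repaired to the nearest
  correlation matrix when not PSD and factored with eigenvalue
  clipping and row renormalization, so each series has exactly unit
  variance and correlations approximate the targets (deviations are
  measured in tests).  Per-subject node positions are jittered (sd
  2 mm) to emulate anatomical variability, and each subject's series
  carries its own geometry, which the analysis uses, as a real
  analysis would use per-subject anatomical distances.
* **Calibration.** The mapping from generating correlation ρ to the
  estimator's W is calibrated empirically: for each ρ on a grid, pairs
  `x = √ρ z + √(1−ρ) e1`, `y = √ρ z + √(1−ρ) e2` are simulated and run
  through the full estimator.  A Fisher-z power heuristic,
  `W ≈ ((z_{0.975}/atanh ρ)² + 3)·T_eff` with
  `T_eff = max(T, 1/(2·bandwidth))`, seeds and backstops the curve;
  the Monte-Carlo estimates refine it, isotonic regression enforces
  monotonicity, and the inverse interpolates in log-log space (the
  mapping is approximately `W ∝ ρ⁻²`).  Two location statistics are
  available: the median (default) and the mean over finite estimates.
  Cohort generation uses the mean statistic because the analysis's
  fitted quantity `W̄` is a conditional mean over observable links;
  median calibration leaves a systematic offset wherever the Ŵ
  distribution is skewed or censored at the 30 s ceiling.  The grid is
  densified (and replicates doubled) below ρ = 0.16, where the mapping
  is steepest and censoring is heaviest.

What the generator does **not** emulate: 1/f spectra, nonstationarity,
artifacts, volume conduction or any forward/inverse field modeling.
Passing tests therefore demonstrate that the estimator and the
downstream statistics recover a known correlation-vs-distance law from
band-limited Gaussian signals — not that any particular neural
mechanism holds in real recordings.

Known structural limits, measured during development: near the 30 s
probing ceiling the estimator's sampling spread censors part of the Ŵ
distribution, so the recoverable conditional mean saturates around
24–25 s; targets beyond that compress slightly, which softens the far
end of the third regime.  And because `γ ≈ m3/W̄(75 mm)`, the
piecewise ground truth that keeps all targets positive yields a
third-regime power-law exponent near 0.3.

## Desk-scale problem sizes

Simulation-heavy runs (the acceptance script and the end-to-end tests)
use a reduced preset chosen once: widths 0.6–30 s (`w0 = 0.6`,
`M = 50` — the full 30 s upper limit is retained, the width grid is
coarsened), 50 FT surrogates (exact for Gaussian signals), synthetic
cohorts at 25 Hz with a 0.5–10 Hz band and 160 s per subject, 72 nodes
and 10 subjects.  The full default (0.2–30 s, 200 iaaft surrogates,
250 Hz) runs identically, only slower and with a finer W grid.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `w0` | 0.2 s | minimum window width and center spacing |
| `M` | 150 | number of widths (`w_max = M·w0` = 30 s) |
| `alpha` | 0.05 | per-window p-value threshold |
| `eta_threshold` | 0.5 | efficiency level a width must overcome |
| `n_surrogates` | 200 | surrogate replicates per pair |
| `surrogate` | iaaft | surrogate construction |
| bins | 25 or 50 | histogram bins per axis |
| `init_d12`, `init_d23` | 44, 68 mm | manual initial breakpoints |
| `d0` | 75 mm | power-law reference distance |
| Bonferroni | 0.05/7 | control-comparison significance level |
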