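"""Cohort-level summaries and the end-to-end pipeline driver.

Per subject: the link ratio R (detected links over available pairs) and
the mean observability time scale.  Across subjects: age-decade averages
of R with a grand-mean 2-sigma band, hemisphere partitioning of the link
table (LL / LR / RR), the control-node-set 2-D KS comparison, and the
full trim -> links -> distributions -> fits pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as obsio
from .diststats import ConditionalCurve, conditional_from_links
from .errors import ConfigurationError, ObscorError
from .ks2d import KS2DResult, bonferroni_gate, ks2d_test
from .observability import assess_links, links_to_frame
from .params import MethodParams
from .regimes import (PiecewiseFit, PowerLawFit, fit_power_law,
                      two_step_piecewise_fit)
from .synthetic import SyntheticConfig, draw_ages, generate_cohort

HEMI_SUBSETS = ("LL", "LR", "RR")
DECADE_START = 18
DECADE_END = 88


# ---------------------------------------------------------------------------
# subject and decade summaries


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    age: float | None
    R: float
    mean_W: float | None
    n_links: int
    n_pairs: int


def subject_summary(links: pd.DataFrame, subject_id: str | None = None,
                    age: float | None = None) -> SubjectSummary:
    """Link ratio R = n_links / n_pairs and mean finite W for one subject."""
    if len(links) == 0:
        raise ValueError("subject has zero node pairs")
    if subject_id is None:
        ids = links["subject_id"].unique()
        if len(ids) != 1:
            raise ValueError("link table spans several subjects")
        subject_id = str(ids[0])
    W = links["W_s"].to_numpy(dtype=float)
    finite = np.isfinite(W)
    n_links = int(finite.sum())
    return SubjectSummary(
        subject_id=subject_id, age=age,
        R=n_links / len(links),
        mean_W=float(W[finite].mean()) if n_links else None,
        n_links=n_links, n_pairs=len(links))


@dataclass(frozen=True)
class DecadeSummary:
    label: str
    lo: int
    hi: int          # inclusive upper age
    mean_R: float
    sem_R: float
    n: int


def decade_summaries(summaries) -> tuple[list[DecadeSummary], float, float]:
    """Average R per age decade (18-27, 28-37, ...) plus the grand mean
    of the decade means and its 2-sigma band half-width.

    Empty decades are reported as absent (not listed); subjects without
    an age are skipped.
    """
    edges = list(range(DECADE_START, DECADE_END - 9, 10))  # 18, 28, ... 78
    buckets: dict[int, list[float]] = {lo: [] for lo in edges}
    for s in summaries:
        if s.age is None:
            continue
        if not DECADE_START <= s.age <= DECADE_END:
            raise ValueError(f"age {s.age} outside [18, 88]")
        lo = edges[min((int(s.age) - DECADE_START) // 10, len(edges) - 1)]
        buckets[lo].append(s.R)
    out = []
    for lo in edges:
        vals = buckets[lo]
        if not vals:
            continue
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        hi = lo + 9 if lo != edges[-1] else DECADE_END  # last bin absorbs 88
        out.append(DecadeSummary(
            label=f"{lo}-{hi}", lo=lo, hi=hi,
            mean_R=float(arr.mean()), sem_R=sem, n=len(arr)))
    means = np.array([d.mean_R for d in out])
    grand = float(means.mean()) if means.size else float("nan")
    band = float(2.0 * means.std(ddof=1)) if means.size > 1 else 0.0
    return out, grand, band


# ---------------------------------------------------------------------------
# hemisphere partition


def hemisphere_partition(links: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a link table into the disjoint LL / LR / RR subsets."""
    if "hemisphere_pair" not in links.columns:
        raise ValueError("link table lacks the hemisphere_pair column")
    pairs = links["hemisphere_pair"]
    bad = set(pairs.unique()) - set(HEMI_SUBSETS)
    if bad:
        raise ValueError(f"unknown hemisphere pairing(s): {sorted(bad)}")
    return {h: links.loc[pairs == h].reset_index(drop=True)
            for h in HEMI_SUBSETS}


# ---------------------------------------------------------------------------
# control node set comparison


@dataclass
class ControlComparison:
    results: list[KS2DResult]
    subject_ids: list[str]
    rejected: np.ndarray
    corrected_level: float

    @property
    def n_rejections(self) -> int:
        return int(self.rejected.sum())


def control_set_comparison(series_sets, nodes, set_a, set_b,
                           params: MethodParams, ks_method: str = "permutation",
                           n_permutations: int = 999, alpha: float = 0.05,
                           seed: int = 0) -> ControlComparison:
    """Compare the (d, W) samples of two disjoint node sets per subject.

    For every subject the link assessment runs on both node subsets; the
    two resulting point clouds are compared with the 2-D KS test and the
    per-subject p-values pass through a Bonferroni gate at ``alpha``.
    """
    set_a, set_b = list(set_a), list(set_b)
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise ValueError(f"node sets overlap: {sorted(overlap)[:5]} ...")
    results, ids = [], []
    for k, ts in enumerate(series_sets):
        samples = []
        for node_set in (set_a, set_b):
            sub = ts.subset(node_set)
            table = sub.nodes if sub.nodes is not None else nodes
            records = assess_links(sub, table, params)
            pts = np.array([[r.d, r.W] for r in records if r.W is not None])
            samples.append(pts)
        res = ks2d_test(samples[0], samples[1], method=ks_method,
                        n_permutations=n_permutations, seed=int(seed) + k)
        results.append(res)
        ids.append(ts.subject_id)
    flags, level = bonferroni_gate([r.p for r in results], alpha=alpha)
    return ControlComparison(results=results, subject_ids=ids,
                             rejected=flags, corrected_level=level)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class FitBundle:
    curve: ConditionalCurve
    piecewise: PiecewiseFit | None
    error: str | None = None


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; loadable from YAML."""

    seed: int = 0
    output_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    series_paths: list[str] = field(default_factory=list)
    node_table_path: str | None = None
    sampling_period: float = 0.004
    ages: list[float] | None = None
    method: MethodParams = field(default_factory=MethodParams)
    n_bins_d: int = 50
    n_bins_W: int = 50
    init_d12: float = 44.0
    init_d23: float = 68.0
    power_law_d0: float = 75.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "ground_truth" in syn and syn["ground_truth"] is not None:
                from .synthetic import GroundTruth

                gt = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in syn["ground_truth"].items()}
                syn["ground_truth"] = GroundTruth(**gt)
            if "noise_band" in syn and syn["noise_band"] is not None:
                syn["noise_band"] = tuple(syn["noise_band"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "method" in kwargs and kwargs["method"] is not None:
            kwargs["method"] = MethodParams(**kwargs["method"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    nodes: "obsio.NodeTable"
    links: pd.DataFrame
    subject_summaries: list[SubjectSummary]
    decades: list[DecadeSummary]
    grand_mean_R: float
    band_2sigma: float
    fits: dict[str, FitBundle]       # All, LL, LR, RR
    power_law: PowerLawFit | None
    manifest: dict


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        nodes, series, gt = generate_cohort(syn, method=config.method)
        ages = draw_ages(len(series), config.seed)
        return nodes, series, list(ages), {"ground_truth": dataclasses.asdict(gt)}
    if not config.node_table_path:
        raise ConfigurationError("config names neither synthetic inputs nor "
                                 "a node table")
    if not config.series_paths:
        raise ConfigurationError("no series files configured")
    nodes = obsio.read_node_table(config.node_table_path)
    series = [obsio.read_series_matrix(p, config.sampling_period)
              for p in config.series_paths]
    ages = config.ages if config.ages is not None else [None] * len(series)
    return nodes, series, list(ages), {}


def _trim_series(ts):
    """Apply the duration-standardization rules to a whole-file series,
    treated as a single epoch; sub-160 s subjects raise."""
    epochs = obsio.select_and_trim_epochs(
        [obsio.Epoch(0, ts.n_samples)], ts.sampling_period)
    return obsio.extract_epochs(ts, epochs)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> PipelineResult:
    """Execute trim -> links -> distributions -> fits -> summaries.

    Fits run on the full link table and on the three hemisphere subsets;
    a subset whose piecewise fit fails is reported with the failure
    message instead of aborting the run.  Deterministic given the seed.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    stage = "inputs"
    try:
        nodes, series, ages, extra = _load_inputs(config)
        stage = "trim"
        series = [_trim_series(ts) for ts in series]
        stage = "links"
        frames, summaries = [], []
        for ts, age in zip(series, ages):
            subj_nodes = ts.nodes if ts.nodes is not None else nodes
            records = assess_links(ts, subj_nodes, config.method)
            frame = links_to_frame(records, ts.subject_id)
            frames.append(frame)
            summaries.append(subject_summary(frame, ts.subject_id, age))
        links = pd.concat(frames, ignore_index=True)
        stage = "distributions_fits"
        fits: dict[str, FitBundle] = {}
        subsets = {"All": links, **hemisphere_partition(links)}
        for name, sub in subsets.items():
            fits[name] = _fit_subset(sub, config)
        stage = "power_law"
        power = None
        all_fit = fits["All"].piecewise
        if all_fit is not None:
            curve = fits["All"].curve
            sel = (curve.d > all_fit.d23) & np.isfinite(curve.Wbar) & \
                (curve.Wbar > 0)
            if sel.sum() >= 3:
                try:
                    power = fit_power_law(curve.d[sel], curve.Wbar[sel],
                                          d0=config.power_law_d0)
                except ObscorError:
                    power = None
        stage = "summaries"
        decades, grand, band = decade_summaries(summaries)
        manifest = {
            "seed": config.seed,
            "method": dataclasses.asdict(config.method),
            "n_subjects": len(series),
            "n_nodes": len(nodes),
            "n_bins": [config.n_bins_d, config.n_bins_W],
            "init_breakpoints_mm": [config.init_d12, config.init_d23],
            **extra,
        }
        result = PipelineResult(
            nodes=nodes, links=links, subject_summaries=summaries,
            decades=decades, grand_mean_R=grand, band_2sigma=band,
            fits=fits, power_law=power, manifest=manifest)
    except ObscorError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    if config.output_dir:
        _write_bundle(result, config)
    return result


def _fit_subset(sub: pd.DataFrame, config: PipelineConfig) -> FitBundle:
    from .errors import EmptyDistributionError, FitFailureError

    try:
        curve = conditional_from_links(sub, n_bins_d=config.n_bins_d,
                                       n_bins_W=config.n_bins_W, log_d=True)
    except EmptyDistributionError as exc:
        empty = ConditionalCurve(x=np.array([]), Wbar=np.array([]),
                                 sd=np.array([]), n=np.array([], dtype=int),
                                 f_W_given_d=np.empty((0, 0)), log_d=True)
        return FitBundle(curve=empty, piecewise=None, error=str(exc))
    try:
        fit = two_step_piecewise_fit(curve, init_d12=config.init_d12,
                                     init_d23=config.init_d23)
        return FitBundle(curve=curve, piecewise=fit)
    except (FitFailureError, ObscorError) as exc:
        return FitBundle(curve=curve, piecewise=None, error=str(exc))


def fits_table(fits: dict[str, FitBundle]) -> pd.DataFrame:
    """Slopes and breakpoints per link subset, one row per condition."""
    rows = []
    for name in ("All", *HEMI_SUBSETS):
        fb = fits.get(name)
        if fb is None or fb.piecewise is None:
            rows.append({"subset": name, "error": None if fb is None
                         else fb.error})
            continue
        f = fb.piecewise
        rows.append({
            "subset": name,
            "m1_s": f.slopes[0], "m2_s": f.slopes[1], "m3_s": f.slopes[2],
            "m1_err": f.slope_errs[0], "m2_err": f.slope_errs[1],
            "m3_err": f.slope_errs[2],
            "d12_mm": f.d12, "d23_mm": f.d23,
            "d12_err": f.d12_err, "d23_err": f.d23_err,
        })
    return pd.DataFrame(rows)


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    obsio.write_node_table(result.nodes, out / "nodes.tsv")
    obsio.write_link_table(result.links, out / "links.tsv")
    fits_table(result.fits).to_csv(out / "fits.tsv", sep="\t", index=False)
    for name, fb in result.fits.items():
        if len(fb.curve.x):
            fb.curve.to_frame().to_csv(out / f"curve_{name}.tsv", sep="\t",
                                       index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in result.subject_summaries]) \
        .to_csv(out / "subjects.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(d) for d in result.decades]) \
        .to_csv(out / "decades.tsv", sep="\t", index=False)
    if result.power_law is not None:
        (out / "power_law.json").write_text(
            json.dumps(dataclasses.asdict(result.power_law), indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                  default=str))
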