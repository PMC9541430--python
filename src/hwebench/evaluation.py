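"""Experiment orchestration: scenarios x schemes x resampled SNP panels.

The full benchmark runs, for every scenario seed: simulate genotypes,
inject RADseq artifacts, apply the universal pre-filters (MAC >= 2,
call rate >= 0.8), build one HWE decision matrix, then for each
filtering scheme apply it, draw SNP panels with replacement, and score
every panel with the structure metrics.  Scheme pairs are then compared
per scenario and metric with Mann-Whitney U tests, BH-adjusted within
each scenario x metric family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, MaskedDataset
from .hwe_filter import FilterConfig, apply_scheme, bh_adjust, build_decision_matrix
from .prefilter import call_rate_filter, mac_filter
from .sim_data import (
    ArtifactConfig,
    ScenarioConfig,
    inject_radseq_artifacts,
    scenario_config,
    simulate_panmictic,
    simulate_stepping_stone,
)
from .structure_metrics import compute_metrics

__all__ = [
    "ExperimentConfig",
    "resample_indices",
    "resample_panels",
    "mann_whitney_u",
    "run_experiment",
    "derive_seeds",
]

logger = logging.getLogger(__name__)

METRICS = ("pcst", "mean_fst", "fis_pooled", "wahlund_slope")


@dataclass
class ExperimentConfig:
    """Grid definition for one benchmark run."""

    scenarios: list[str] = field(
        default_factory=lambda: ["panmictic", "marginal", "low", "high", "extreme"]
    )
    schemes: list[FilterConfig] = field(
        default_factory=lambda: [
            FilterConfig("no_filter"),
            FilterConfig("out_any"),
            FilterConfig("out_all"),
            FilterConfig("out_some", out_some_min=3),
            FilterConfig("out_within"),
            FilterConfig("out_combo"),
        ]
    )
    artifacts: ArtifactConfig | None = field(default_factory=ArtifactConfig)
    n_resamples: int = 10
    panel_size: int = 4000
    n_sim_replicates: int = 10
    alpha_compare: float = 0.05
    master_seed: int = 0
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.panel_size < 1 or self.n_resamples < 1 or self.n_sim_replicates < 1:
            raise ValueError("panel_size, n_resamples, n_sim_replicates must be >= 1")


def derive_seeds(master_seed: int, n: int, label: str = "") -> list[int]:
    """Deterministically split a master seed into n child seeds (< 2**31).

    The split hashes the label so independent stages of the pipeline
    never share a stream.
    """
    key = np.frombuffer(label.encode() or b"\x00", dtype=np.uint8)
    ss = np.random.SeedSequence([int(master_seed), *key.tolist()])
    return [int(s) for s in (ss.generate_state(n, dtype=np.uint32) >> 1)]


def resample_indices(
    n_loci: int, panel_size: int, n_resamples: int, seed: int
) -> list[np.ndarray]:
    """Column indices for panels drawn uniformly with replacement."""
    if n_loci < 1:
        raise ValueError("cannot resample from an empty locus set")
    rng = np.random.default_rng(seed)
    return [
        np.sort(rng.integers(0, n_loci, size=panel_size)) for _ in range(n_resamples)
    ]


def _panel_from_indices(g: GenotypeMatrix, idx: np.ndarray) -> GenotypeMatrix:
    """Build a panel matrix; duplicated draws become duplicate columns.

    Panel loci get fresh IDs and sequential positions (duplicates would
    otherwise collide); the original locus ID is kept in a ``source``
    column so per-population masks can be carried through.
    """
    loci = g.loci.iloc[idx].copy()
    loci["source"] = loci.index
    loci.index = pd.Index([f"p{k:05d}" for k in range(len(idx))], name="locus")
    loci["pos"] = np.arange(1, len(idx) + 1) * 100
    loci["chrom"] = "1"
    return GenotypeMatrix(list(g.samples), loci, g.calls[:, idx].copy())


def resample_panels(
    g: GenotypeMatrix, panel_size: int, n_resamples: int, seed: int
) -> list[GenotypeMatrix]:
    """Draw ``n_resamples`` SNP panels of ``panel_size`` loci with replacement."""
    return [
        _panel_from_indices(g, idx)
        for idx in resample_indices(g.n_loci, panel_size, n_resamples, seed)
    ]


def _panel_masked(md: MaskedDataset, idx: np.ndarray) -> MaskedDataset:
    panel = _panel_from_indices(md.genotypes, idx)
    masks: dict[str, set[str]] = {}
    for pop, banned in md.masks.items():
        if banned:
            src = panel.loci["source"]
            masks[pop] = set(panel.loci.index[src.isin(banned)])
        else:
            masks[pop] = set()
    return MaskedDataset(genotypes=panel, popmap=md.popmap, masks=masks)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midranks for ties).

    Uses the exact null distribution when both samples have at most 10
    values and no ties straddle them; otherwise the normal
    approximation with tie and continuity corrections.  Identical
    constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _simulate(name: str, seed: int, overrides: dict) -> tuple:
    if name == "panmictic":
        cfg = scenario_config(name, seed=seed, **overrides)
        return simulate_panmictic(cfg, n_pseudopops=6)
    cfg = scenario_config(name, seed=seed, **overrides)
    return simulate_stepping_stone(cfg)


def run_scenario_seed(
    scenario: str,
    seed: int,
    schemes: list[FilterConfig],
    artifacts: ArtifactConfig | None,
    panel_size: int,
    n_resamples: int,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """One simulation replicate scored under every scheme and panel."""
    overrides = overrides or {}
    sim_seed, art_seed, panel_seed = derive_seeds(seed, 3, "scenario")
    g, popmap = _simulate(scenario, sim_seed, overrides)
    if artifacts is not None:
        art = ArtifactConfig(
            null_locus_prob=artifacts.null_locus_prob,
            null_freq_max=artifacts.null_freq_max,
            geno_error_rate=artifacts.geno_error_rate,
            missing_rate=artifacts.missing_rate,
            seed=art_seed,
        )
        g = inject_radseq_artifacts(g, art)
    g = call_rate_filter(mac_filter(g, 2), 0.8)
    alphas = {c.alpha for c in schemes}
    decisions = {a: build_decision_matrix(g, popmap, alpha=a, pooled=True) for a in alphas}
    rows = []
    for cfg in schemes:
        md = apply_scheme(g, popmap, decisions[cfg.alpha], cfg)
        indices = resample_indices(md.genotypes.n_loci, panel_size, n_resamples, panel_seed)
        for k, idx in enumerate(indices):
            panel = _panel_masked(md, idx)
            try:
                rec = compute_metrics(panel)
            except ValueError as exc:
                logger.warning(
                    "%s seed=%d scheme=%s panel=%d failed: %s",
                    scenario, seed, cfg.scheme, k, exc,
                )
                continue
            rows.append(
                {
                    "scenario": scenario,
                    "seed": seed,
                    "scheme": cfg.scheme,
                    "panel": k,
                    "pcst": rec.pcst,
                    "mean_fst": rec.mean_fst,
                    "fis_pooled": rec.fis_pooled,
                    "wahlund_slope": rec.wahlund_slope,
                    "n_loci_available": md.genotypes.n_loci,
                }
            )
    return pd.DataFrame(rows)


def compare_schemes(metrics: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise scheme comparisons per scenario x metric.

    The statistical unit is the per-panel metric value pooled across
    simulation seeds; BH adjustment is applied within each scenario x
    metric family.
    """
    rows = []
    for scenario, sub in metrics.groupby("scenario", sort=False):
        schemes = list(pd.unique(sub["scheme"]))
        for metric in METRICS:
            if metric not in sub.columns:
                continue
            family = []
            for sa, sb in itertools.combinations(schemes, 2):
                x = sub.loc[sub["scheme"] == sa, metric].dropna().to_numpy()
                y = sub.loc[sub["scheme"] == sb, metric].dropna().to_numpy()
                if x.size == 0 or y.size == 0:
                    continue
                u, p = mann_whitney_u(x, y)
                family.append(
                    {
                        "scenario": scenario,
                        "metric": metric,
                        "scheme_a": sa,
                        "scheme_b": sb,
                        "U": u,
                        "p_value": p,
                    }
                )
            if family:
                q = bh_adjust(np.array([f["p_value"] for f in family]))
                for f, qv in zip(family, q):
                    f["q_value"] = float(qv)
                    f["significant"] = bool(qv < alpha)
                rows.extend(family)
    return pd.DataFrame(rows)


def summarize_medians(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median of each metric per scenario x scheme (the 'red line' summary)."""
    cols = [m for m in METRICS if m in metrics.columns]
    return (
        metrics.groupby(["scenario", "scheme"], sort=False)[cols]
        .median()
        .reset_index()
    )


def run_experiment(cfg: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full grid; returns (per-panel metrics, comparison table).

    Any scenario x scheme stage failure is logged and the grid
    continues.  Fully deterministic under ``master_seed``.
    """
    seeds = derive_seeds(cfg.master_seed, cfg.n_sim_replicates, "experiment")
    frames = []
    for scenario in cfg.scenarios:
        for seed in seeds:
            try:
                frames.append(
                    run_scenario_seed(
                        scenario,
                        seed,
                        cfg.schemes,
                        cfg.artifacts,
                        cfg.panel_size,
                        cfg.n_resamples,
                        overrides=cfg.scenario_overrides,
                    )
                )
            except Exception as exc:  # keep the grid alive
                logger.error("scenario %s seed %d failed: %s", scenario, seed, exc)
    metrics = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    comparisons = (
        compare_schemes(metrics, alpha=cfg.alpha_compare)
        if not metrics.empty
        else pd.DataFrame()
    )
    return metrics, comparisons
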