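"""Population-structure metrics: PC_ST, Weir-Cockerham F_ST, F_IS.

Three inference surfaces are computed on a genotype matrix plus popmap:

* **PC_ST** — one minus the ratio of the mean within-population
  Euclidean distance to the mean distance over all sample pairs, in the
  space of the first 10 principal components of the scaled genotype
  matrix.  0 for an unstructured cloud, towards 1 for tight separated
  clusters.
* **Weir-Cockerham theta** — the 1984 variance-component estimator of
  F_ST, computed per locus with full unequal-sample-size handling and
  combined across loci as a ratio of sums; pairwise values between all
  population pairs and their mean.
* **pooled F_IS** = 1 - H_O/H_t over the sample pooled into a single
  population, and the ordinary-least-squares slope of per-locus F_IS on
  per-locus F_ST — positive under a Wahlund effect, where pooling
  differentiated demes depresses heterozygosity exactly at the loci
  that carry the structure signal.

Missing data policy: PCA imputes missing calls to the locus mean; the
F-statistics use observed genotype counts only and never imputed
values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genotype_io import MISSING, GenotypeMatrix, MaskedDataset, PopMap, apply_mask

__all__ = [
    "MetricsRecord",
    "scale_genotypes",
    "pca_scores",
    "pcst",
    "wc_fst_pair",
    "mean_pairwise_fst",
    "fis_pooled",
    "per_locus_fis",
    "per_locus_fst",
    "wahlund_slope",
    "compute_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsRecord:
    """Per-dataset summary of the three inference surfaces."""

    pcst: float
    mean_fst: float
    fst_matrix: pd.DataFrame
    fis_pooled: float
    wahlund_slope: float
    n_loci_used: int


def scale_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Mean-impute, centre and unit-variance scale the call matrix.

    Missing calls are replaced by the locus mean of non-missing calls;
    each column is centred and divided by its population (ddof=0)
    standard deviation.  Zero-variance columns are dropped with a
    logged count.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = g.calls.astype(float)
    observed = g.calls != MISSING
    n_called = observed.sum(axis=0)
    usable = n_called > 0
    with np.errstate(invalid="ignore"):
        means = np.where(usable, np.where(observed, calls, 0.0).sum(axis=0) / n_called, 0.0)
    x = np.where(observed, calls, means[None, :])
    x = x - means[None, :]
    sd = x.std(axis=0, ddof=0)
    keep = usable & (sd > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance loci before PCA", n_dropped)
    if not keep.any():
        raise ValueError("no polymorphic loci to scale")
    return x[:, keep] / sd[None, keep]


def pca_scores(g: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """Sample scores on the leading principal components of the scaled matrix."""
    x = scale_genotypes(g)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_pcs, rank)
    if k < 1:
        raise ValueError("scaled matrix has rank 0")
    return u[:, :k] * s[:k]


def pcst(g: GenotypeMatrix, popmap: PopMap, n_pcs: int = 10,
         total: str = "all") -> float:
    """PC_ST: 1 - mean within-population distance / mean total distance.

    Distances are Euclidean over the first ``n_pcs`` PCA score
    dimensions.  ``total`` selects the denominator: ``"all"`` averages
    over every unordered sample pair (the default), ``"between"`` over
    between-population pairs only.
    """
    popmap.check_against(g)
    idx_by_pop = popmap.indices_by_pop(g)
    if len(idx_by_pop) < 2:
        raise ValueError("PC_ST needs at least 2 populations")
    for pop, idx in idx_by_pop.items():
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
    scores = pca_scores(g, n_pcs=n_pcs)
    dmat = squareform(pdist(scores))
    labels = np.empty(g.n_samples, dtype=object)
    for pop, idx in idx_by_pop.items():
        labels[idx] = pop
    iu = np.triu_indices(g.n_samples, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    d = dmat[iu]
    within = d[same].mean()
    denom = d.mean() if total == "all" else d[~same].mean()
    return float(1.0 - within / denom)


def _pop_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n called, alt frequency, observed het fraction) for one pop."""
    observed = calls != MISSING
    n = observed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(observed, calls, 0).sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def wc_variance_components(
    calls_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-locus variance components a, b, c.

    ``a`` is the among-population component, ``b`` among individuals
    within populations, ``c`` within individuals.  Loci that are not
    estimable (fewer than 2 called individuals in a population,
    monomorphic across all populations, or degenerate n_c) come back
    NaN in all three components.
    """
    r = len(calls_by_pop)
    if r < 2:
        raise ValueError("need at least 2 populations")
    stats = [_pop_stats(c) for c in calls_by_pop]
    n = np.stack([s[0] for s in stats])  # (r, n_loci)
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])
    ok = (n >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n.sum(axis=0)
        n_bar = n_sum / r
        n_c = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1)
        p_bar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / n_sum
        pq = p_bar * (1.0 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    poly = (p_bar > 0) & (p_bar < 1)
    valid = ok & poly & (n_bar > 1) & (n_c > 0) & np.isfinite(a + b + c)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def _theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    valid = np.isfinite(a)
    denom = (a + b + c)[valid].sum()
    if not valid.any() or denom == 0:
        return float("nan")
    return float(a[valid].sum() / denom)


def wc_fst_pair(
    g: GenotypeMatrix,
    popmap: PopMap,
    pop_a: str,
    pop_b: str,
    masks: dict[str, set[str]] | None = None,
) -> float:
    """Multi-locus pairwise Weir-Cockerham theta between two populations.

    Under "out within" masking, only loci unmasked in *both*
    populations of the pair contribute.  Negative estimates are
    reported as computed, never clipped.
    """
    idx = popmap.indices_by_pop(g)
    for pop in (pop_a, pop_b):
        if pop not in idx:
            raise ValueError(f"population {pop!r} not in popmap")
    keep = np.ones(g.n_loci, dtype=bool)
    if masks:
        banned = set(masks.get(pop_a, ())) | set(masks.get(pop_b, ()))
        if banned:
            keep = ~g.loci.index.isin(banned)
    a, b, c = wc_variance_components(
        [g.calls[idx[pop_a]][:, keep], g.calls[idx[pop_b]][:, keep]]
    )
    return _theta_from_components(a, b, c)


def mean_pairwise_fst(
    g: GenotypeMatrix,
    popmap: PopMap,
    masks: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """All pairwise thetas and their mean over unordered population pairs.

    Pairs with no usable loci are NaN in the matrix and excluded from
    the mean with a warning.
    """
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs at least 2 populations")
    mat = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    values = []
    for pa, pb in itertools.combinations(pops, 2):
        theta = wc_fst_pair(g, popmap, pa, pb, masks=masks)
        mat.loc[pa, pb] = mat.loc[pb, pa] = theta
        if np.isfinite(theta):
            values.append(theta)
        else:
            logger.warning("pair (%s, %s) has no usable loci; excluded from mean", pa, pb)
    if not values:
        raise ValueError("no population pair had usable loci")
    return mat, float(np.mean(values))


def _pooled_het(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus observed het fraction and pooled expected het 2p(1-p)."""
    n, p, h_o = _pop_stats(g.calls)
    h_t = 2.0 * p * (1.0 - p)
    h_o = np.where(n > 0, h_o, np.nan)
    h_t = np.where(n > 0, h_t, np.nan)
    return h_o, h_t


def fis_pooled(g: GenotypeMatrix) -> float:
    """Multi-locus F_IS = 1 - sum(H_O)/sum(H_t) over the pooled sample."""
    h_o, h_t = _pooled_het(g)
    valid = np.isfinite(h_t)
    total_ht = h_t[valid].sum()
    if total_ht == 0:
        raise ValueError("no heterozygosity expected anywhere; F_IS undefined")
    return float(1.0 - h_o[valid].sum() / total_ht)


def per_locus_fis(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus pooled F_IS = 1 - H_O/H_t (NaN where H_t = 0)."""
    h_o, h_t = _pooled_het(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = 1.0 - h_o / h_t
    return np.where(h_t > 0, fis, np.nan)


def per_locus_fst(g: GenotypeMatrix, popmap: PopMap) -> np.ndarray:
    """Per-locus multi-population Weir-Cockerham theta (NaN where undefined)."""
    idx = popmap.indices_by_pop(g)
    a, b, c = wc_variance_components([g.calls[i] for i in idx.values()])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return np.where(np.isfinite(theta), theta, np.nan)


def wahlund_slope(
    g: GenotypeMatrix, popmap: PopMap, orientation: str = "fis_on_fst"
) -> float:
    """OLS slope relating per-locus pooled F_IS and per-locus F_ST.

    The default regresses F_IS on F_ST, the direction in which a
    Wahlund effect predicts a positive slope; ``orientation=
    "fst_on_fis"`` gives the reverse regression.
    """
    fis = per_locus_fis(g)
    fst = per_locus_fst(g, popmap)
    valid = np.isfinite(fis) & np.isfinite(fst)
    if valid.sum() < 3:
        raise ValueError("too few loci with both F_IS and F_ST defined")
    y, x = (fis[valid], fst[valid]) if orientation == "fis_on_fst" else (fst[valid], fis[valid])
    if np.ptp(x) == 0:
        return float("nan")
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def compute_metrics(
    md: MaskedDataset, n_pcs: int = 10
) -> MetricsRecord:
    """Evaluate all metrics on one (possibly masked) dataset.

    PC_ST and the pooled F_IS / Wahlund regression use the
    mask-applied matrix (masked calls missing); pairwise F_ST excludes
    loci masked in either member of each pair.
    """
    g = apply_mask(md) if md.has_masks else md.genotypes
    fst_matrix, mean_fst = mean_pairwise_fst(
        md.genotypes, md.popmap, masks=md.masks if md.has_masks else None
    )
    return MetricsRecord(
        pcst=pcst(g, md.popmap, n_pcs=n_pcs),
        mean_fst=mean_fst,
        fst_matrix=fst_matrix,
        fis_pooled=fis_pooled(g),
        wahlund_slope=wahlund_slope(g, md.popmap),
        n_loci_used=g.n_loci,
    )
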