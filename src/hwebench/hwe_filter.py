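"""Hardy-Weinberg testing within strata and the five filtering schemes.

Loci are tested for HWE departure with a Pearson chi-square test (1 df,
no continuity correction) within each stratum — each population, plus
optionally the pooled sample — and p-values are Benjamini-Hochberg
adjusted across loci within each stratum.  The resulting boolean
decision matrix (stratum x locus "departs after FDR") feeds the five
locus-removal rules:

================  ====================================================
``no_filter``     keep everything
``out_any``       drop loci departing in at least one population
``out_all``       drop loci departing in every population
``out_some``      drop loci departing in at least ``out_some_min``
                  populations
``out_within``    mask each locus only in the populations where it
                  departs (no global drops)
``out_combo``     drop loci departing in the pooled sample — the
                  default behaviour of popmap-unaware tools, and the
                  one vulnerable to the Wahlund effect
================  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, GenotypeMatrix, MaskedDataset, PopMap

__all__ = [
    "POOLED",
    "SCHEMES",
    "FilterConfig",
    "DecisionMatrix",
    "hwe_chisq",
    "hwe_chisq_counts",
    "bh_adjust",
    "build_decision_matrix",
    "apply_scheme",
]

#: sentinel stratum label for the pooled (popmap-ignorant) sample
POOLED = "POOLED"

SCHEMES = ("no_filter", "out_any", "out_all", "out_some", "out_within", "out_combo")


@dataclass
class FilterConfig:
    """Scheme choice plus its parameters.

    ``out_some_min`` may be an absolute stratum count (int >= 2) or a
    proportion in (0, 1), converted to a count by ceiling against the
    number of populations.
    """

    scheme: str = "no_filter"
    alpha: float = 0.05
    out_some_min: int | float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.scheme == "out_some" and self.out_some_min is None:
            raise ValueError("out_some requires out_some_min")

    def resolve_min(self, n_strata: int) -> int:
        v = self.out_some_min
        if isinstance(v, float) and 0.0 < v < 1.0:
            v = ceil(v * n_strata)
        v = int(v)
        if not (1 < v < n_strata):
            raise ValueError(
                f"out_some_min must resolve to a count strictly between 1 and "
                f"{n_strata} (got {v})"
            )
        return v


@dataclass
class DecisionMatrix:
    """Boolean strata x loci table of FDR-significant HWE departures.

    ``table.loc[s, l]`` is True when locus ``l`` departs from HWE in
    stratum ``s`` at ``alpha`` after BH adjustment across the loci of
    that stratum.  ``results`` carries the full per-test record
    (genotype counts, chi2, p, q) for reporting.
    """

    table: pd.DataFrame
    alpha: float
    correction_scope: str = "per-stratum BH across loci"
    results: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def strata(self) -> list[str]:
        return list(self.table.index)

    @property
    def loci(self) -> list[str]:
        return list(self.table.columns)

    def population_strata(self) -> list[str]:
        return [s for s in self.table.index if s != POOLED]


def hwe_chisq_counts(
    n_homref: np.ndarray, n_het: np.ndarray, n_homalt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-square HWE test on genotype counts.

    Expected counts are n*p^2, 2n*p*q, n*q^2 with the allele frequency
    estimated from the counts themselves; 1 degree of freedom, no
    continuity correction.  Monomorphic input gives (0, 1).
    """
    n_homref = np.asarray(n_homref, dtype=float)
    n_het = np.asarray(n_het, dtype=float)
    n_homalt = np.asarray(n_homalt, dtype=float)
    n = n_homref + n_het + n_homalt
    if np.any(n < 1):
        raise ValueError("HWE test undefined for empty genotype counts")
    p = (2 * n_homref + n_het) / (2 * n)
    q = 1.0 - p
    poly = (p > 0) & (q > 0)
    chi2 = np.zeros_like(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_rr = n * p * p
        e_ra = 2 * n * p * q
        e_aa = n * q * q
        raw = (
            (n_homref - e_rr) ** 2 / e_rr
            + (n_het - e_ra) ** 2 / e_ra
            + (n_homalt - e_aa) ** 2 / e_aa
        )
    chi2[poly] = raw[poly]
    pval = stats.chi2.sf(chi2, df=1)
    pval[~poly] = 1.0
    return chi2, pval


def hwe_chisq(n_homref: int, n_het: int, n_homalt: int) -> tuple[float, float]:
    """Scalar HWE chi-square test; see :func:`hwe_chisq_counts`."""
    chi2, p = hwe_chisq_counts(
        np.array([n_homref]), np.array([n_het]), np.array([n_homalt])
    )
    return float(chi2[0]), float(p[0])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p_values, method="fdr_bh")[1]


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (calls == 0).sum(axis=0),
        (calls == 1).sum(axis=0),
        (calls == 2).sum(axis=0),
    )


def build_decision_matrix(
    g: GenotypeMatrix,
    popmap: PopMap,
    alpha: float = 0.05,
    pooled: bool = True,
) -> DecisionMatrix:
    """Test every locus for HWE departure within every stratum.

    Strata are the popmap's populations plus, when ``pooled``, the
    whole sample under the :data:`POOLED` label.  Within each stratum
    p-values are BH-adjusted across all its loci (loci monomorphic in
    the stratum enter with p = 1 and are never significant, keeping the
    correction's m equal to the number of loci).
    """
    popmap.check_against(g)
    rows_by_pop = popmap.indices_by_pop(g)
    strata: dict[str, np.ndarray] = {p: g.calls[idx] for p, idx in rows_by_pop.items()}
    if pooled:
        strata[POOLED] = g.calls
    records = []
    departs_rows = {}
    for name, calls in strata.items():
        observed = calls != MISSING
        n_called = observed.sum(axis=0)
        if np.all(n_called < 2):
            raise ValueError(
                f"stratum {name!r} has fewer than 2 called individuals at every locus"
            )
        # loci with zero calls in this stratum are untestable; score p=1
        rr, ra, aa = _genotype_counts(calls)
        testable = n_called >= 1
        chi2 = np.zeros(g.n_loci)
        pval = np.ones(g.n_loci)
        if testable.any():
            chi2[testable], pval[testable] = hwe_chisq_counts(
                rr[testable], ra[testable], aa[testable]
            )
        qval = bh_adjust(pval)
        departs = qval < alpha
        departs_rows[name] = departs
        records.append(
            pd.DataFrame(
                {
                    "stratum": name,
                    "locus": g.loci.index,
                    "n_homref": rr,
                    "n_het": ra,
                    "n_homalt": aa,
                    "chi2": chi2,
                    "p_value": pval,
                    "q_value": qval,
                    "departs": departs,
                }
            )
        )
    table = pd.DataFrame(departs_rows, index=g.loci.index).T
    return DecisionMatrix(
        table=table, alpha=alpha, results=pd.concat(records, ignore_index=True)
    )


def apply_scheme(
    g: GenotypeMatrix,
    popmap: PopMap,
    D: DecisionMatrix,
    cfg: FilterConfig,
) -> MaskedDataset:
    """Apply one of the five HWE filtering schemes.

    Globally dropped loci are removed from the matrix; ``out_within``
    instead returns per-population masks and drops nothing.  The result
    is always a :class:`MaskedDataset` (empty masks except for
    ``out_within``).
    """
    popmap.check_against(g)
    pops = [p for p in popmap.populations]
    scheme = cfg.scheme
    if scheme == "out_combo":
        if POOLED not in D.table.index:
            raise ValueError("out_combo requires a POOLED stratum in the decision matrix")
    elif scheme != "no_filter":
        absent = [p for p in pops if p not in D.table.index]
        if absent:
            raise ValueError(f"decision matrix lacks population strata: {absent}")

    locus_ids = list(g.loci.index)
    sub = D.table.reindex(columns=locus_ids)
    masks: dict[str, set[str]] = {p: set() for p in pops}
    if scheme == "no_filter":
        drop = np.zeros(len(locus_ids), dtype=bool)
    elif scheme == "out_combo":
        drop = sub.loc[POOLED].to_numpy(dtype=bool)
    else:
        per_pop = sub.loc[pops].to_numpy(dtype=bool)
        n_departing = per_pop.sum(axis=0)
        if scheme == "out_any":
            drop = n_departing >= 1
        elif scheme == "out_all":
            drop = n_departing == len(pops)
        elif scheme == "out_some":
            drop = n_departing >= cfg.resolve_min(len(pops))
        else:  # out_within
            drop = np.zeros(len(locus_ids), dtype=bool)
            for i, p in enumerate(pops):
                masks[p] = {l for l, d in zip(locus_ids, per_pop[i]) if d}
    kept = g.subset_loci(~drop)
    return MaskedDataset(genotypes=kept, popmap=popmap, masks=masks)
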