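"""Universal SNP pre-filters applied before any HWE-based filtering.

Two locus-level filters: a minor-allele-count filter (default 2, so
singletons are removed but doubletons retained) and a call-rate filter
(default 0.8, removing sites with more than 20% missing calls; exactly
20% missing is retained).  Both are idempotent, commute, and never touch
the sample set.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["mac_filter", "call_rate_filter", "minor_allele_counts", "call_rates"]


def minor_allele_counts(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor-allele count over non-missing calls."""
    calls = g.calls
    observed = calls != MISSING
    alt = np.where(observed, calls, 0).sum(axis=0)
    total = 2 * observed.sum(axis=0)
    return np.minimum(alt, total - alt)


def call_rates(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of samples with a non-missing call."""
    if g.n_samples == 0:
        return np.zeros(g.n_loci)
    return (g.calls != MISSING).sum(axis=0) / g.n_samples


def mac_filter(g: GenotypeMatrix, min_mac: int = 2) -> GenotypeMatrix:
    """Drop loci whose minor-allele count is below ``min_mac``.

    Monomorphic loci (MAC 0) are removed whenever ``min_mac >= 1``.
    """
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    return g.subset_loci(minor_allele_counts(g) >= min_mac)


def call_rate_filter(g: GenotypeMatrix, min_call_rate: float = 0.8) -> GenotypeMatrix:
    """Drop loci called in less than ``min_call_rate`` of samples (boundary kept)."""
    if not (0.0 <= min_call_rate <= 1.0):
        raise ValueError("min_call_rate must be in [0, 1]")
    return g.subset_loci(call_rates(g) >= min_call_rate)
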