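"""Synthetic genotype generators with stepping-stone population structure.

Three generators cover the study conditions:

* :func:`simulate_stepping_stone` — a reduced forward-time Wright-Fisher
  model on a linear chain of demes with Poisson-distributed migrant
  exchange between adjacent demes.  The migration rate M sets the degree
  of population structure (M = 0.1 marginal ... 0.0001 extreme).
* :func:`simulate_panmictic` — a single random-mating population whose
  sample is split into arbitrary "pseudopopulations" carrying no genetic
  signal, the null control for spurious-structure detection.
* :func:`simulate_balding_nichols` — Beta-distributed deme allele
  frequencies around a shared ancestral frequency, whose expected
  Weir-Cockerham F_ST equals the divergence parameter F; used for
  estimator parameter-recovery checks.

:func:`inject_radseq_artifacts` overlays reduced-representation
sequencing pathologies (null alleles acting on haplotypes, genotyping
error, random missingness) on any genotype matrix.

All loci are unlinked: each locus is an independent allele-frequency
trajectory, and genotypes are drawn from within-deme Hardy-Weinberg
proportions at sampling time (the model's random-mating assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopMap

__all__ = [
    "ScenarioConfig",
    "ArtifactConfig",
    "SCENARIO_MIGRATION_RATES",
    "scenario_config",
    "simulate_stepping_stone",
    "simulate_panmictic",
    "simulate_balding_nichols",
    "inject_radseq_artifacts",
]

#: named degrees of population structure and their migration rates
SCENARIO_MIGRATION_RATES: dict[str, float] = {
    "panmictic": 0.0,
    "marginal": 0.1,
    "low": 0.01,
    "high": 0.001,
    "extreme": 0.0001,
}


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults are the desk-scale study conditions: 12 demes of 100
    diploids evolving 500 generations at 5000 unlinked loci, with 30
    individuals sampled from every other deme (180 total).
    """

    n_demes: int = 12
    deme_size: int = 100
    migration_rate: float = 0.001
    n_generations: int = 500
    n_loci: int = 5000
    mutation_rate: float = 1e-5
    sampled_demes: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    sample_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.migration_rate <= 0.5):
            raise ConfigurationError("migration_rate must be in [0, 0.5]")
        for name in ("n_demes", "deme_size", "n_generations", "n_loci", "sample_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not all(0 <= d < self.n_demes for d in self.sampled_demes):
            raise ConfigurationError("sampled_demes must index existing demes")
        if len(set(self.sampled_demes)) != len(self.sampled_demes):
            raise ConfigurationError("sampled_demes must be distinct")
        if self.sample_size > self.deme_size:
            raise ConfigurationError("sample_size exceeds deme_size")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ConfigurationError("mutation_rate must be in [0, 0.5)")


def scenario_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build the config for a named scenario (panmictic/marginal/low/high/extreme).

    The panmictic scenario uses a single larger deme so that 180
    individuals can be drawn from one random-mating population.
    """
    if name not in SCENARIO_MIGRATION_RATES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_MIGRATION_RATES)}"
        )
    m = SCENARIO_MIGRATION_RATES[name]
    if name == "panmictic":
        base = dict(
            n_demes=1, deme_size=500, migration_rate=0.0,
            sampled_demes=(0,), sample_size=180,
        )
    else:
        base = dict(migration_rate=m)
    base.update(overrides)
    return ScenarioConfig(seed=seed, **base)


@dataclass
class ArtifactConfig:
    """Genotype-level RADseq artifact model.

    ``null_locus_prob`` of loci carry a hidden null allele with
    frequency drawn uniform(0, ``null_freq_max``); a visible/null
    heterozygote is read as homozygous for the visible allele and a
    null/null individual as missing.  Independently, true heterozygotes
    are miscalled as a random homozygote with ``geno_error_rate`` and
    calls drop out at random with ``missing_rate``.
    """

    null_locus_prob: float = 0.3
    null_freq_max: float = 0.3
    geno_error_rate: float = 0.01
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("null_locus_prob", "null_freq_max", "geno_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")


def _locus_table(n_loci: int, rng: np.random.Generator) -> pd.DataFrame:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    ids = [f"snp{i:06d}" for i in range(n_loci)]
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_loci + 1) * 100,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        },
        index=pd.Index(ids, name="locus"),
    )


def _mutate(p: np.ndarray, mu: float) -> np.ndarray:
    # recurrent biallelic flip keeps loci from permanent fixation
    return p * (1.0 - mu) + (1.0 - p) * mu


def _evolve_frequencies(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Run the Wright-Fisher chain; return (n_loci, n_demes) final frequencies.

    Each generation: (1) adjacent demes swap a Poisson(deme_size x
    migration_rate) number of individuals, the swap holding deme sizes
    constant; the alleles the migrants carry are Binomial draws from the
    source deme's frequency; (2) each deme reproduces by binomial
    resampling of 2N gametes; (3) recurrent mutation nudges frequencies.
    Loci are independent columns throughout.
    """
    n2 = 2 * cfg.deme_size
    # standing variation shared across demes at the split
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    p = np.repeat(p0[:, None], cfg.n_demes, axis=1)
    pairs = [(i, i + 1) for i in range(cfg.n_demes - 1)]
    lam = cfg.deme_size * cfg.migration_rate
    for _ in range(cfg.n_generations):
        if lam > 0 and pairs:
            counts = np.zeros((cfg.n_loci, cfg.n_demes))
            counts[:] = p * n2
            for i, j in pairs:
                m = int(min(rng.poisson(lam), cfg.deme_size))
                if m == 0:
                    continue
                k_i = rng.binomial(2 * m, p[:, i])
                k_j = rng.binomial(2 * m, p[:, j])
                counts[:, i] += k_j - k_i
                counts[:, j] += k_i - k_j
            p = np.clip(counts, 0, n2) / n2
        p = rng.binomial(n2, p) / n2
        if cfg.mutation_rate > 0:
            p = _mutate(p, cfg.mutation_rate)
    return p


def _sample_genotypes(
    freqs: np.ndarray, n_per_pop: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw HW genotypes: (n_pops*n_per_pop, n_loci) from (n_loci, n_pops) freqs."""
    blocks = [
        rng.binomial(2, np.repeat(freqs[:, [d]], n_per_pop, axis=1)).T
        for d in range(freqs.shape[1])
    ]
    return np.vstack(blocks).astype(np.int8)


def simulate_stepping_stone(cfg: ScenarioConfig) -> tuple[GenotypeMatrix, PopMap]:
    """Simulate the linear stepping-stone scenario and sample it.

    Returns genotypes for ``sample_size`` diploids from each deme in
    ``sampled_demes`` plus a popmap labelling each sample by its deme of
    origin (``pop01`` ... in deme order).  Identical config and seed
    give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _evolve_frequencies(cfg, rng)
    sampled = freqs[:, list(cfg.sampled_demes)]
    calls = _sample_genotypes(sampled, cfg.sample_size, rng)
    loci = _locus_table(cfg.n_loci, rng)
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for k, deme in enumerate(cfg.sampled_demes):
        pop = f"pop{deme + 1:02d}"
        for i in range(cfg.sample_size):
            name = f"{pop}_ind{i + 1:03d}"
            samples.append(name)
            assignments[name] = pop
    return GenotypeMatrix(samples, loci, calls), PopMap(assignments)


def simulate_panmictic(
    cfg: ScenarioConfig, n_pseudopops: int = 6
) -> tuple[GenotypeMatrix, PopMap]:
    """Simulate one panmictic population split into label-only pseudopopulations.

    The total sample (``sample_size`` x ``len(sampled_demes)``
    individuals, all drawn from a single Wright-Fisher deme) is assigned
    round-robin to ``n_pseudopops`` labels that carry no genetic signal.
    """
    total = cfg.sample_size * len(cfg.sampled_demes)
    if n_pseudopops < 1 or total % n_pseudopops != 0:
        raise ConfigurationError(
            f"total sample size {total} not divisible into {n_pseudopops} pseudopopulations"
        )
    if total > cfg.deme_size:
        raise ConfigurationError("total sample exceeds deme_size")
    one = ScenarioConfig(
        n_demes=1,
        deme_size=cfg.deme_size,
        migration_rate=0.0,
        n_generations=cfg.n_generations,
        n_loci=cfg.n_loci,
        mutation_rate=cfg.mutation_rate,
        sampled_demes=(0,),
        sample_size=cfg.deme_size,
        seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    freqs = _evolve_frequencies(one, rng)
    calls = _sample_genotypes(freqs, total, rng)
    loci = _locus_table(cfg.n_loci, rng)
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for i in range(total):
        pop = f"pseudo{(i % n_pseudopops) + 1}"
        name = f"ind{i + 1:03d}"
        samples.append(name)
        assignments[name] = pop
    return GenotypeMatrix(samples, loci, calls), PopMap(assignments)


def simulate_balding_nichols(
    F: float,
    n_pops: int = 6,
    n_per_pop: int = 30,
    n_loci: int = 4000,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopMap]:
    """Draw genotypes under the Balding-Nichols divergence model.

    Per locus an ancestral frequency p ~ uniform(0.05, 0.95) is drawn;
    each deme's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so the
    expected Weir-Cockerham F_ST of the output equals ``F``.  Genotypes
    follow Hardy-Weinberg proportions within demes.
    """
    if not (0.0 < F < 1.0):
        raise ConfigurationError("F must be in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_loci)
    scale = (1.0 - F) / F
    freqs = rng.beta(
        np.repeat((p * scale)[:, None], n_pops, axis=1),
        np.repeat(((1.0 - p) * scale)[:, None], n_pops, axis=1),
    )
    calls = _sample_genotypes(freqs, n_per_pop, rng)
    loci = _locus_table(n_loci, rng)
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for d in range(n_pops):
        pop = f"pop{d + 1:02d}"
        for i in range(n_per_pop):
            name = f"{pop}_ind{i + 1:03d}"
            samples.append(name)
            assignments[name] = pop
    return GenotypeMatrix(samples, loci, calls), PopMap(assignments)


def inject_radseq_artifacts(
    g: GenotypeMatrix, a: ArtifactConfig, return_info: bool = False
):
    """Overlay null-allele, genotyping-error and missingness artifacts.

    The null allele operates on haplotypes so the artifact has correct
    Hardy-Weinberg structure: at an affected locus each of an
    individual's two haplotypes is independently null with the locus's
    null frequency; one null haplotype hides a het as a visible-allele
    homozygote, two yield a missing call.  With all probabilities zero
    the output equals the input.  Deterministic under ``a.seed``.

    With ``return_info`` the null-allele bookkeeping is also returned:
    a dict with ``null_loci`` (IDs of loci carrying a null allele) and
    ``null_freq`` (per-locus null frequencies, 0 at unaffected loci).
    """
    rng = np.random.default_rng(a.seed)
    out = g.copy()
    info = {"null_loci": [], "null_freq": np.zeros(g.n_loci)}
    calls = out.calls
    n, m = calls.shape

    if a.null_locus_prob > 0 and a.null_freq_max > 0:
        affected = rng.random(m) < a.null_locus_prob
        u = np.where(affected, rng.uniform(0.0, a.null_freq_max, size=m), 0.0)
        info["null_loci"] = list(g.loci.index[affected])
        info["null_freq"] = u
        # which of the two haplotypes carry the null, per call
        h1 = rng.random((n, m)) < u
        h2 = rng.random((n, m)) < u
        observed = calls != MISSING
        both = h1 & h2 & observed
        one = (h1 ^ h2) & observed
        het = calls == 1
        # visible haplotype of a het: the one not nulled
        # h1 ~ reference-carrying haplotype, h2 ~ alternate-carrying (hets only)
        calls[one & het & h1] = 2  # ref haplotype hidden -> looks alt-hom
        calls[one & het & h2] = 0
        # homozygotes with one null haplotype look unchanged
        calls[both] = MISSING

    if a.geno_error_rate > 0:
        het = calls == 1
        err = het & (rng.random((n, m)) < a.geno_error_rate)
        calls[err] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(err.sum()))

    if a.missing_rate > 0:
        drop = rng.random((n, m)) < a.missing_rate
        calls[drop] = MISSING

    return (out, info) if return_info else out
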