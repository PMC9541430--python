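"""Genotype containers and VCF / popmap input-output.

The pipeline's universal currency is a diploid biallelic genotype matrix:
individuals in rows, SNP loci in columns, each call the count of
alternate alleles (0, 1, 2) or :data:`MISSING`.  Population assignments
come from a Stacks-style popmap (``sample<TAB>population``).  The
"out within" filtering scheme additionally needs per-population locus
masks, represented by :class:`MaskedDataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopMap",
    "MaskedDataset",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_masks",
    "write_masks",
    "apply_mask",
]

logger = logging.getLogger(__name__)

#: sentinel genotype value for a missing call
MISSING: int = -1

_LOCI_COLUMNS = ("chrom", "pos", "ref", "alt")


class FormatError(ValueError):
    """Raised for unreadable or inconsistent input files."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls for a set of samples.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``calls``).
    loci
        DataFrame indexed by locus ID with columns ``chrom``, ``pos``,
        ``ref``, ``alt`` (columns of ``calls``).  Extra columns are
        carried along untouched.
    calls
        ``(n_samples, n_loci)`` int8 array of alternate-allele counts;
        ``-1`` marks a missing call.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if not self.loci.index.is_unique:
            raise ValueError("duplicate locus IDs")
        missing_cols = set(_LOCI_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci table lacks columns: {sorted(missing_cols)}")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci.index)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.loci.copy(), self.calls.copy())

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to loci selected by boolean/positional index."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.samples), self.loci.iloc[keep].copy(), self.calls[:, keep].copy()
        )

    def sample_indices(self, names: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=np.intp)


@dataclass
class PopMap:
    """Mapping of sample ID to population (sampling-location) label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("popmap is empty")

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def check_against(self, g: GenotypeMatrix) -> None:
        """Require every genotype sample to carry exactly one label."""
        missing = [s for s in g.samples if s not in self.assignments]
        if missing:
            raise FormatError(
                f"{len(missing)} sample(s) in genotypes absent from popmap: "
                f"{missing[:5]}"
            )

    def indices_by_pop(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Row indices into ``g.calls`` for each population, in popmap order."""
        self.check_against(g)
        present = set(g.samples)
        out: dict[str, list[str]] = {}
        for s, p in self.assignments.items():
            if s in present:
                out.setdefault(p, []).append(s)
        return {p: g.sample_indices(names) for p, names in out.items()}


@dataclass
class MaskedDataset:
    """Genotypes plus per-population locus masks.

    ``masks[pop]`` is the set of locus IDs treated as missing within
    that population.  Empty masks everywhere is the valid no-op state,
    which every filtering scheme except "out within" produces.
    """

    genotypes: GenotypeMatrix
    popmap: PopMap
    masks: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.popmap.check_against(self.genotypes)
        known = set(self.genotypes.loci.index)
        for pop, loci in self.masks.items():
            unknown = set(loci) - known
            if unknown:
                raise ValueError(
                    f"mask for {pop!r} references unknown loci: {sorted(unknown)[:5]}"
                )

    @property
    def has_masks(self) -> bool:
        return any(self.masks.get(p) for p in self.masks)


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF (v4.2) file.

    Multi-allelic and non-SNP records are skipped (a count is logged).
    ``./.`` and ``.|.`` become missing; phasing is ignored; haploid or
    polyploid GT fields cause the record to be skipped with a warning.
    """
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    ids: list[str] = []
    meta: list[tuple] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        ploidy = rec.ploidy
        if ploidy != 2:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        columns.append(g)
    if n_skipped:
        logger.warning("skipped %d non-biallelic/non-SNP/non-diploid records", n_skipped)
    loci = pd.DataFrame(meta, columns=list(_LOCI_COLUMNS), index=pd.Index(ids, name="locus"))
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(g.loci["chrom"])
        for chrom in chroms:
            max_pos = int(g.loci.loc[g.loci["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, (locus_id, row) in enumerate(g.loci.iterrows()):
            gts = "\t".join(_GT_STRINGS[int(v)] for v in g.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{locus_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_popmap(path: str) -> PopMap:
    """Parse a ``sample<TAB>population`` popmap; duplicate samples are an error."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            sample, pop = parts
            if sample in assignments:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    return PopMap(assignments)


def write_popmap(popmap: PopMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def read_masks(path: str) -> dict[str, set[str]]:
    """Read a two-column (population, locus ID) TSV of masked loci."""
    masks: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'population<TAB>locus'")
            masks.setdefault(parts[0], set()).add(parts[1])
    return masks


def write_masks(masks: dict[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for pop in sorted(masks):
            for locus in sorted(masks[pop]):
                fh.write(f"{pop}\t{locus}\n")


def apply_mask(md: MaskedDataset) -> GenotypeMatrix:
    """Materialise per-population masks as missing calls.

    Returns a copy of the genotype matrix in which every masked
    (population, locus) call is set to missing; unmasked entries are
    never altered.  With empty masks this is the identity.
    """
    g = md.genotypes.copy()
    if not md.has_masks:
        return g
    col_of = {locus: j for j, locus in enumerate(g.loci.index)}
    rows_by_pop = md.popmap.indices_by_pop(g)
    for pop, loci in md.masks.items():
        if pop not in rows_by_pop or not loci:
            continue
        rows = rows_by_pop[pop]
        cols = np.array([col_of[l] for l in loci], dtype=np.intp)
        g.calls[np.ix_(rows, cols)] = MISSING
    return g
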