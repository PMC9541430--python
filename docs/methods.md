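# Methods

## The question

Reduced-representation sequencing studies (RADseq, DArTseq) routinely
filter SNPs for departure from Hardy–Weinberg equilibrium (HWE), but the
*stratification* of that test is rarely reported and often left at tool
defaults. The choice matters: testing HWE on the pooled sample ("out
combo", the default of popmap-unaware tools) preferentially removes loci
whose allele frequencies differ among populations, because pooling
differentiated demes depresses heterozygosity at exactly those loci (the
Wahlund effect). `hwebench` quantifies how each of the five stratification
choices distorts downstream inference of population structure, using a
fully synthetic pipeline so every stage is reproducible and testable.

## Simulation model

### Stepping-stone scenarios

A linear (non-circular) chain of `n_demes = 12` Wright–Fisher demes of
`deme_size = 100` diploids evolves for `n_generations = 500` at
`n_loci = 5000` unlinked biallelic loci. Initial allele frequencies are
drawn uniform(0.05, 0.95) once per locus and shared across demes
(standing variation at the split). Each generation:

1. **Migration.** Every adjacent pair of demes swaps
   `m ~ Poisson(deme_size x migration_rate)` individuals (the swap holds
   deme sizes constant; end demes have one neighbour). The alleles the
   migrants carry are binomial draws from the source deme's current
   frequency, which is exact for randomly chosen migrants under
   within-deme random mating.
2. **Reproduction.** Each deme's next-generation frequency is a
   binomial draw of `2N` gametes (standard Wright–Fisher resampling).
3. **Mutation.** Recurrent symmetric flips at `mutation_rate = 1e-5`
   per locus per generation keep loci from fixing permanently at the
   reduced population size; loci fixed in the sample are later removed
   by the MAC filter, mirroring how monomorphic sites drop out of a real
   SNP panel.

At the end, 30 diploids are sampled from every other deme (6 demes, 180
individuals) with genotypes drawn from within-deme Hardy–Weinberg
proportions — the model's random-mating assumption, which also makes the
within-deme HWE test's null exactly true for artifact-free loci.

Because loci are unlinked, the whole simulation reduces to independent
per-locus frequency trajectories; this is the per-locus marginal of an
individual-based Wright–Fisher model and runs in seconds where an
explicit genome simulation takes hours. What is deliberately *not*
modelled: linkage (and therefore the contrast between recombination
regimes), age structure, selection, and read-level error processes.
Conclusions about those features of real data are outside what the
passing tests demonstrate.

The migration rate sets the degree of structure; the named scenarios are
`marginal` (M = 0.1), `low` (0.01), `high` (0.001) and `extreme`
(0.0001). At desk scale these give mean pairwise Weir–Cockerham F_ST of
roughly 0.06, 0.30, 0.65 and 0.86 — a steeper gradient than a
1000-diploid simulation would give (F_ST scales with 1/(1 + 4Nm)), but
the benchmark's object of study is the *relative* behaviour of filtering
schemes along the gradient, which is preserved.

The `panmictic` scenario is a single 500-diploid deme whose 180-sample
is split round-robin into six "pseudopopulations"; the labels carry no
genetic signal, making it the null control for spurious structure.

### Balding–Nichols calibration generator

For estimator tests a faster generator draws each deme's allele
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral
p ~ uniform(0.05, 0.95). Its expected Weir–Cockerham F_ST equals F by
construction, giving a closed-form parameter-recovery oracle: at
F = 0.1 with 6 demes x 30 diploids x 4000 loci the multi-locus estimate
lands within ±0.02 of 0.1 in at least 9 of 10 seeds.

### RADseq artifact model

`ArtifactConfig` overlays three genotype-level pathologies:

* **Null alleles** (`null_locus_prob = 0.3`, frequency
  u ~ uniform(0, 0.3) per affected locus): each of an individual's two
  haplotypes is independently null with probability u. One null
  haplotype hides a heterozygote as a homozygote for the visible allele;
  two produce a missing call. Operating on haplotypes rather than calls
  keeps the artifact's Hardy–Weinberg structure correct — the apparent
  genotype distribution is exactly that of a locus with a third,
  invisible allele, which is the pathology the per-population HWE filter
  exists to catch.
* **Genotyping error** (`geno_error_rate = 0.01`): a true heterozygote
  is miscalled as a random homozygote.
* **Missingness** (`missing_rate = 0.05`): calls drop out uniformly.

With `geno_error_rate = 0`, injection can only reduce observed
heterozygosity (a tested invariant). Defaults approximate a moderately
noisy reduced-representation dataset; the null-allele intensity is mild
(mean u = 0.15), so per-population detection power at n = 30 is partial
— about a third of affected loci are flagged after FDR correction.

## Filtering pipeline

Pre-filters follow standard practice: minor allele count >= 2 computed
over non-missing calls (singletons removed, doubletons kept), then call
rate >= 0.8, with the boundary (exactly 20% missing) retained.

HWE testing is a Pearson chi-square on the three genotype counts against
n·p², 2n·p·q, n·q² (1 df, no continuity correction — the chi-square
column of pegas-style `hw.test`). For a biallelic locus this statistic
equals n·F̂² with F̂ = 1 − H_O/H_E, an identity the tests exploit.
P-values are Benjamini–Hochberg adjusted **across loci within each
stratum separately** (strata stay exchangeable and m equals the number
of loci); loci monomorphic in a stratum enter with p = 1 rather than
being excluded from m. The pooled stratum is tested alongside the
per-population strata so that `out_combo` and the per-population schemes
share one decision matrix.

Scheme semantics are pure set operations on that boolean matrix and are
verified against brute-force per-locus enumeration. `out_some`
thresholds on "departing in at least k populations" (a proportion is
converted to a count by ceiling), so `drops(out_all) ⊆ drops(out_some)
⊆ drops(out_any)` always holds. `out_within` drops nothing globally; it
masks each flagged locus only in the population where it was flagged.

## Metrics

* **PC_ST** = 1 − (mean within-population Euclidean distance)/(mean
  distance over *all* sample pairs), computed on sample scores over the
  first 10 principal components of the scaled genotype matrix (missing
  calls mean-imputed per locus, columns centred and scaled to unit
  population variance, zero-variance columns dropped). The denominator
  includes within-population pairs; a `total="between"` switch gives the
  between-pairs-only variant.
* **Weir–Cockerham θ̂** uses the full 1984 variance components a, b, c
  with unequal sample sizes, combined over loci as Σa/Σ(a+b+c); loci
  monomorphic across a pair, with fewer than two called individuals in
  either member, or masked in either member (under `out_within`) are
  skipped. Negative estimates are reported as computed. The headline
  statistic is the mean of the pairwise θ̂ over all unordered population
  pairs.
* **Pooled F_IS** = 1 − ΣH_O/ΣH_t with H_t = 2p(1−p) from pooled allele
  frequencies. The **Wahlund diagnostic** regresses per-locus pooled
  F_IS on per-locus multi-population θ̂ by OLS; a Wahlund effect
  predicts a positive slope. The regression direction follows that
  expectation (the reverse orientation is exposed as an option). Note
  that null alleles create a genuine genome-wide F_IS signal of their
  own, so the diagnostic's null calibration belongs on artifact-free
  panmictic data.

F-statistics never use imputed genotypes; imputation exists only for the
PCA.

## Experiment design

Per scenario seed: simulate → inject artifacts → pre-filter → build one
decision matrix → apply each scheme → draw 10 SNP panels of 4000 loci
uniformly with replacement from the scheme's filtered locus set → score
every panel. Panels sampled with replacement at panel size = pool size
retain ≈ 63.2% unique loci (the bootstrap signature, a tested property).
Scheme pairs are compared per scenario x metric with two-sided
Mann–Whitney U tests over the per-panel values pooled across simulation
seeds (10 seeds x 10 panels), BH-adjusted within each scenario x metric
family. All seeds derive from a single master seed through labelled
`SeedSequence` splits, so the entire grid is reproducible bit-for-bit.

## Numerical choices and degenerate inputs

* Missing genotype sentinel −1 in an int8 matrix; VCF `./.` and `.|.`
  map to it, phasing ignored; non-biallelic, non-SNP and non-diploid
  records are skipped with a logged count.
* Chi-square with zero expected heterozygosity (monomorphic stratum)
  returns (0, 1); a stratum with fewer than two called individuals at
  every locus is an error.
* PCA rank is determined by a singular-value tolerance scaled to machine
  epsilon; scores use min(10, rank) components.
* Mann–Whitney switches to the exact null only when both samples have
  ≤ 10 values and no ties; two identical constant samples return p = 1.
* Population pairs with no usable loci are excluded from the mean
  pairwise F_ST with a warning; an all-pairs failure is an error.

## Known limitations

* The F_ST gradient is steeper than at the full population sizes the
  scenarios emulate; absolute metric values are not comparable to
  empirical systems, only scheme-relative behaviour is.
* The spurious-structure effect of `out_any` in panmixia is real but
  small at the default artifact intensity (removal of null-allele loci,
  whose θ̂ is slightly deflated in unstructured data, shifts mean F_ST
  up by ~1e-4); with 10 resampled panels per seed its per-seed sign is
  not reliably resolved, while `out_within` shows the effect
  consistently.
* Model-based clustering (STRUCTURE-style) comparisons are out of scope;
  the metric set covers PCA- and F-statistic-based inference.
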