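# Methods

This note documents the statistical procedures, the synthetic world the
package simulates, and the choices made where more than one defensible
convention exists. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genotype quality control

Markers are excluded, in order: call rate < 0.95; folded MAF < 0.05
(computed from mean dosage / 2); Hardy–Weinberg exact p < 10⁻⁶; HWE p < 10⁻⁴
with no heterozygotes or no minor-allele homozygotes; HWE p < 10⁻³ with
fewer than 6 heterozygotes or minor-allele homozygotes; non-autosomal
chromosome; all members of any (chrom, pos) collision; imputation info score
< 0.5 when the field is present. The order matters and the exclusion report
records one count per step.

The HWE test is the exact conditional test: given the observed allele
counts, it sums the probabilities of all heterozygote configurations no more
probable than the observed one. The exact test is standard QC practice at
small n and is verifiable by full enumeration, which the test suite does. A
chi-square variant is available via `hwe_method="chisq"`. HWE operates on
hard calls obtained by rounding dosages half away from zero — the test is
defined on genotype counts, while every association model consumes the
continuous dosages unchanged.

## Expression preprocessing

Order of operations: probe filters → outlier-sample removal → (log2 if the
input is raw intensity) quantile normalization → expression PCs → per-probe
rank-based inverse normal transform (INT), applied last before model
fitting.

* **Probe filters.** Probes flagged as multi-mapping or containing a common
  SNP are dropped, as are probes whose detection p ≥ 0.01 in *every* sample
  (one detected sample suffices to keep a probe).
* **Variance-stabilizing transform is omitted.** VST is array-chemistry
  specific; the pipeline's entry point is a generic expression matrix, and
  log2 + quantile normalization + INT preserve the rank structure the
  association model uses. The run report carries this as a deviation flag.
* **Quantile normalization** replaces each sample's sorted values with the
  across-sample mean of sorted values; ties within a sample receive the mean
  of the reference values over the tied ranks, making the result
  deterministic.
* **INT** maps the value of rank r (average ranks for ties) to
  Φ⁻¹((r − c)/(n + 1 − 2c)) with c = 3/8 for n ≤ 10 and c = 1/2 otherwise —
  the plotting-position convention of R's `ppoints`/`qqnorm`.
* **Outlier samples** are flagged quantitatively (the historical practice
  this replaces was visual heat-map inspection): a sample whose mean
  Spearman correlation to all others falls more than 3 SD (default) below
  the across-sample mean is removed, and the procedure iterates exactly
  once.
* **Expression PCs** are computed on the quantile-normalized (pre-INT),
  probe-centered matrix. The number of PCs k is chosen from a grid by
  running the full cis scan at each k and keeping the k that maximizes the
  number of probes with ≥ 1 cis association at a single FDR level (default
  0.05); ties break toward smaller k. Counts at the full FDR grid are
  reported so multi-threshold behavior is visible.

## eQTL mapping

A SNP–probe pair is **cis** iff the SNP is on the gene's chromosome with
position in [min(TSS, TES) − 1 Mb, max(TSS, TES) + 1 Mb], bounds inclusive;
otherwise **trans**. Signed distances are SNP − TSS, oriented so positive
means downstream in the gene's strand direction.

Each pair is fit by exact OLS of INT expression on [intercept, dosage,
covariates]; t = β/se on n − (k + 2) df. The scan residualizes expression
and dosage on the covariates once (QR) and evaluates the per-pair slope
test, which is numerically identical to the full per-pair OLS by
Frisch–Waugh–Lovell; the test suite checks agreement with a naive
normal-equations solve to 1e−8. Constant-dosage SNPs are skipped with a
logged count. BH q-values are computed separately within the cis and trans
classes.

**Stepwise conditional signals.** For each probe significant at the chosen
FDR, the most significant cis SNP's dosage is added to the covariates and
the probe's remaining cis SNPs are rescanned, until the minimum remaining p
exceeds the stepwise threshold or the design loses identifiability. The
threshold is the *realized BH cutoff* — the largest unconditional p among
associations passing the chosen FDR level — which ties the stepwise count to
the same FDR level as the headline table; it is recorded in the run report.
A relative tolerance of 1e−9 on the threshold comparison absorbs
last-ulp differences between the global scan and the per-probe rescan
(different BLAS summation orders). The conditional scan covers only the
probe's cis SNPs, not the genome.

## Population genetics

* **Ancestry PCA**: SNP columns centered by 2p̂ and scaled by
  √(2p̂(1 − p̂)), monomorphic SNPs dropped, SVD, components ordered by
  variance; each PC's sign is fixed so its largest-magnitude SNP loading is
  positive, making results reproducible across linear-algebra backends. PC1
  of an LD-pruned panel serves as the ancestry covariate.
* **LD r²** is the squared Pearson correlation of dosages (composite,
  phase-free). Proxy search returns all SNPs within 500 kb (default) at
  r² ≥ 0.8, always including the target itself. Pruning is a greedy
  sliding-window pass that removes the later-positioned member of any
  retained pair above the r² ceiling — deterministic given input order.
* **F<sub>ST</sub>** is Weir–Cockerham's two-population unbiased estimator
  from observed genotype counts: variance components a (between
  populations), b (between individuals within populations), c (within
  individuals, h̄/2), θ̂ = a/(a + b + c). Negative θ̂ values are reported
  as-is; truncation would bias averages. **Combining loci uses the ratio of
  summed components Σa/Σ(a+b+c)**: the mean of per-SNP ratios is biased
  toward zero when only two populations are compared (the between-population
  component has one degree of freedom), an effect the test suite
  demonstrates at F = 0.2. Per-SNP θ̂ is used unmodified for the
  differentiation thresholds (θ̂ > 0.25 for high differentiation; > 0.10 for
  trait-overlap reporting; both strict inequalities).

## Matched-resampling enrichment

Null SNP sets match the target set's size and its exact per-bin occupancy
over folded MAF (bins of width 0.05) and |distance to nearest TSS|
(half-decade log bins from 1 bp to 10 Mb plus a zero bin). Matching on both
dimensions is the default; either can be disabled. Sampling is without
replacement within a set and independent across sets; the pool is the whole
analysis universe (a sampled set may share SNPs with the target, as when
sampling from all study SNPs). A bin with too few candidates is widened to
its nearest nonempty neighbor and logged — never silently under-filled.

* **Trait enrichment**: observed = number of trait SNPs whose best cis p
  (minimum over that SNP's cis pairs; SNPs with no cis pair count as
  non-eQTL) is below 0.001; empirical p = (1 + #{null ≥ obs})/(N + 1). The
  add-one, ties-significant rule is deliberately conservative and bounded
  away from zero; a strict-exceedance rule would declare the degenerate
  all-zero case significant.
* **Two-layer analyses** draw one SNP per significant gene, uniformly among
  that gene's significant cis SNPs, independently across sets (layer 1), and
  matched random sets against one representative layer-1 set (layer 2). The
  histone-peak comparison uses the all-pairs rule p = #{(i, j): null_j ≥
  eqtl_i}/N², reported as below-resolution when the numerator is zero; the
  F<sub>ST</sub> comparison uses a two-sided Mann–Whitney U between the two
  count vectors (normal approximation with tie correction). The FDR level
  feeding the F<sub>ST</sub> layer is a required parameter of the pipeline
  config rather than a silent default.

SNP-in-peak lookups compare 1-based SNP positions against 0-based half-open
BED intervals (position p is inside iff start ≤ p − 1 < end); this is the
only place the ±1 conversion occurs.

## The synthetic world

The generator's defaults describe a small admixed eQTL cohort:

| parameter | default | rationale |
|---|---|---|
| individuals | 100 | small-cohort eQTL regime |
| SNPs / genes / chromosome | 1,000 / 100 / 50 Mb | one synthetic chromosome; gene density leaves each gene's ±1 Mb window with a few dozen SNPs |
| target F<sub>ST</sub> | 0.1 | continental-scale differentiation |
| admixture Beta(8, 2) | mean 80% population-1 ancestry | two-way admixed cohort |
| planted cis genes | 50, each explaining 30% of expression variance | detectable but not trivial at n = 100 |
| noise sd | 1.0 (log2-intensity-like scale, baseline 8) | microarray-like dynamic range |
| peak sets | 2 kb peaks, 5% background coverage, 5× coverage of planted eQTL | active-mark-like genome coverage |
| trait list | 50 SNPs, 100% planted overlap | positive-control GWAS list; a MAF-matched null list accompanies it |

Genotypes follow the Balding–Nichols model: per-SNP ancestral frequency
p ~ U[0.05, 0.95], population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), each
allele drawn from population 1 with probability equal to the individual's
ancestry proportion. Genotypes are hard calls in {0, 1, 2}; the pipeline
nonetheless treats genotype columns as continuous dosages throughout, so the
dosage code path is exercised (fractional dosages enter via VCF/TSV input).
Planted effect sizes are scaled against the realized dosage variance so the
genotype term explains the configured variance fraction in expectation;
planted SNPs are distinct across genes, require realized folded MAF ≥ 0.05
(a near-monomorphic SNP would receive a divergent coefficient from the
variance scaling), and, when two are planted per gene, have pairwise
r² < 0.05. In the noiseless limit (no residual variance) the
coefficient is set to an arbitrary positive constant — expression is then an
exact affine function of dosage.

All randomness flows from one integer seed through named substreams
(`simulate.substream(seed, name)`), so each stage regenerates independently
of execution order and identical configs give byte-identical outputs.

**What the generator does not emulate** — and what a green test therefore
does not establish: realistic LD block structure (no haplotype coalescent;
LD arises only from shared ancestry), microarray intensity-level noise and
background, probe-sequence artifacts, multiple chromosomes by default, and
sample sizes beyond the hundreds. Enrichment power results on this world say
nothing about catalogs whose trait SNPs tag causal variants only through
fine-scale LD.

Two stated-world caveats surfaced by testing: (i) the "every SNP passes
MAF ≥ 0.05 up to sampling fluctuation" property holds where the ancestral
frequency is the cohort's true frequency (F = 0); at F ≥ 0.05 the
Balding–Nichols scatter itself pushes part of the frequency distribution
below 0.05, which the QC MAF filter then removes, as intended. (ii) The
F<sub>ST</sub> recovery checks use the multi-locus ratio-of-sums combination
for the reason given above.

## Numerical conventions and degenerate inputs

* Missing dosages are NaN, never 0; they leave denominators in QC statistics
  and are dropped pairwise in LD computations.
* An all-missing SNP gets call rate 0 and undefined (NaN) statistics.
* θ̂ is undefined (NaN, flagged) when a + b + c = 0 (monomorphic in both
  panels); SNPs without an F<sub>ST</sub> estimate leave the denominator of
  differentiation fractions with a logged count.
* Constant expression vectors are rejected by INT (ranks undefined);
  constant dosages are skipped by the scan and rejected by the single-pair
  fit.
* BH q-values are capped at 1 and are monotone nondecreasing in p within a
  class.
* Empirical p-values can never be exactly 0 (add-one rule) and are
  reproducible given the seed.

## Known limitations

Single-threaded dense scans (fine to ~10⁶ pairs; no Matrix-eQTL-style
out-of-core machinery); no mixed models or kinship correction; no
permutation-based per-gene FDR; two-population F<sub>ST</sub> only; no
haplotype phasing; genotype imputation and probe-to-transcriptome alignment
are upstream of this package — imputed dosages and probe flags are inputs.
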