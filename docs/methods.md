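# Methods

## Model and test

The data for one gene are n subjects × t SNVs of minor-allele counts
g<sub>ij</sub> ∈ {0, 1, 2}. Each subject is recoded as a t × 3 indicator
table (rows SNVs, columns minor-allele count); every row margin is 1 and
the table total is t. Conditioning on all margins — the same device as
Fisher's exact test — makes the table's null law the multiple
hypergeometric distribution, which for unit row margins is simply the
uniform distribution over the distinct arrangements of the column labels
across rows. No large-sample approximation enters at this stage, which is
what makes the approach usable at very small n.

**Within-group statistic.** The generalized CMH statistic for the stack of
one group's tables is the quadratic form G′ Var(G|H₀)⁺ G with
G = Σᵢ A(nᵢ − mᵢ). The exact conditional moments are, in row-major
(SNV-major) vectorization,

- mᵢ = t · (P_row ⊗ P_col), with P_row = (1/t, …, 1/t) and
  P_col = column margins / t;
- Var(nᵢ|H₀) = t²/(t−1) · (D_{P_row} − P_row P_row′) ⊗ (D_{P_col} − P_col P_col′).

A = (I_{t−1} | 0) ⊗ (I₂ | 0) removes the redundant last SNV row and the
k = 2 column (df = 2(t−1)). Subjects are independent strata: G and
Var(G|H₀) are accumulated over subjects and only the pooled covariance is
inverted. The analytical moments are pinned against a brute-force
enumeration of the hypergeometric null (all margin-consistent tables,
probabilities evaluated term by term) for every column-margin composition
up to t = 8, at 1e-10.

**Between-group statistic.** T = log CMH_case − log CMH_control. Under the
null of no association between gene and phenotype, labels are
exchangeable, so the permutation distribution of T is the exact reference:
p = (1 + #{b : |T_b| ≥ |T_obs|}) / (B_defined + 1), a finite-sample valid
estimator that never returns 0. Two-sidedness in |T| reflects that no
direction of the ratio is hypothesized.

**Normal shortcut.** The permutation null of T is empirically close to
normal. The shortcut estimates its mean and standard deviation from a
small number of permutations (B_small ≥ 10, default 100; 20 already gives
R² > 0.9 against full permutation on study-sized data) and evaluates the
same rejection rule under the fitted normal:

p = P_{N(μ̂, σ̂²)}(|X| ≥ |T_obs|) = Φ̄((|T_obs| − μ̂)/σ̂) + Φ((−|T_obs| − μ̂)/σ̂).

Two points matter here. First, the moments are *estimated*, not assumed
zero-mean: with unbalanced groups (e.g. 21 vs 23) the permutation null of
T is symmetric about a slightly negative mean, because the smaller group's
statistic runs systematically lower; the offset grows with the information
content of the gene (μ̂/σ̂ up to ≈1 for large, common-variant genes).
Second, the fitted normal is used as the *null law of T itself*, keeping
the shortcut consistent with the permutation reference in exactly those
off-center cases; a rule symmetric about μ̂ (2Φ̄(|T_obs − μ̂|/σ̂)) coincides
with ours when μ̂ ≈ 0 but tests a different region when it is not, and its
agreement with the permutation reference collapses (R² ≈ 0.6 vs ≈ 0.96 on
our 250-gene diagnostic). When σ̂ = 0 the p-value is 1 if T_obs equals μ̂
and flagged otherwise.

**Single-SNV genes.** A 1 × 3 table admits no within-subject contrast, so
genes with t = 1 use an exact test of the 2 × 3 group × genotype table:
all tables with the observed margins are enumerated and those no more
probable than the observed one are summed (probability-ordering two-sided
rule, no mid-p correction). Empty genotype columns are collapsed first;
2 × 2 collapses reproduce the classical hypergeometric two-sided Fisher
p-value.

## Degenerate and missing data

- **Zero statistics.** A group whose subjects are all monomorphic across
  the gene (or a numerically zero statistic, ≤ 1e-12) makes T = ±∞; such
  genes are flagged `undefined_T` and such permutations are excluded from
  the null with a recorded count, rather than poisoning the moments.
- **Rank deficiency.** Var(G|H₀) is generically singular (monomorphic
  variants, alleles never observed at count 2). The quadratic form uses
  the Moore–Penrose pseudo-inverse with singular values below
  1e-10 × σ_max treated as zero, and sets a `degenerate` flag. G lies in
  the range of Var(G|H₀) almost surely, so the zero law (statistic = 0 iff
  G = 0) is preserved.
- **Missing genotypes.** Policy enum: `fail` (default — the test needs
  complete rows; the error names subject and variant), `drop_variant`,
  `drop_subject`; drops are logged per gene. VCF input codes ALT dosage,
  flips any variant with pooled ALT frequency above 0.5 to minor-allele
  dosage (logged), splits multi-allelic sites into bi-allelic records
  (third alleles become missing), and treats `./.` as missing.
- **Seeding.** One master seed; per-gene streams derive from it by stable
  hashing (CRC-32) of the gene id, so per-gene results do not depend on
  analysis order and reruns are bit-identical.

## Computation

Per gene, the pooled reduced covariance factorizes as a Kronecker product
t²/(t−1) · R ⊗ ΣᵢCᵢ with R = I/t − J/t² of order t−1 (R⁻¹ = t(I + J)) and
Cᵢ the subject's 2 × 2 reduced column factor. The statistic therefore
reduces to (t−1)/t · [tr(M′M C⁺) + s′C⁺s] where M is the group's summed
centered table and s its column sums — only 2 × 2 pseudo-inverses per
label assignment. Thousands of permutations evaluate as a few BLAS calls;
equality with the plain matrix path is pinned by tests at 1e-9. Full
permutation at B = 10,000 over a 411-gene, 44-subject study takes seconds.

## Synthetic data

The generator emulates a small targeted-sequencing study and the null
simulation design used to check calibration:

- **Null regions**: a 5-kb region with variant density 0.003/bp (Poisson,
  mean 15 variants — the median gene size of the motivating panel); MAFs
  from Beta(0.3, 3) truncated to [1/(2n), 0.5] (rare-biased but with a
  common tail, since the test targets both); genotypes Hardy–Weinberg,
  either independent across sites or with first-order LD via a
  Gaussian-copula AR(1) haplotype chain (ρ configurable); labels assigned
  by random permutation at a 50/50 split, independent of genotypes — so
  the null holds by construction and every rejection is a type-I error.
  Variants monomorphic in the sample are removed; fully degenerate draws
  are resampled (cap 10).
- **Study fixture**: 44 subjects (21 cases / 23 controls), gene sizes
  log-normal with median 15 clipped to 1..188 (at least one single-SNV
  gene and one with t ≥ 100 guaranteed), same MAF spectrum. A configurable
  fraction of genes is made non-null by raising the case-group MAF of a
  random third of their SNVs to 0.45: cases then carry a hot-spot
  partial-association pattern that controls lack — the
  differential-intensity alternative the log-ratio statistic targets
  (power ≈ 0.35 at α = 0.05 under these sizes).

What the generator does **not** emulate: realistic haplotype structure
beyond first-order LD, site-frequency spectra from demography, sequencing
or genotyping error, population stratification, or covariate effects.
Passing calibration and fidelity checks on these data therefore shows the
statistic and its p-value machinery behave correctly under the stated
sampling model; it does not certify behavior under confounding or
structured LD.

## Scales and defaults used by the built-in studies

- Type-I-error study default: R = 1000 replicates, normal-approximation
  p-values at B_small = 100 (the acceptance script uses R = 4000, the
  full simulation size, since a replicate costs ~1 ms). Rejection rates
  are reported with binomial standard errors; replicates with an
  untestable region are excluded from the denominator and counted.
- Shortcut-fidelity diagnostic: reference permutation p-values at
  B = 2000 (noise SE ≤ 0.011 per gene) against shortcut p-values at
  B_small = 20, across ≥ 200 multi-SNV genes; the panel also reports
  Kolmogorov–Smirnov p, MSE, Pearson and Spearman correlations across a
  grid of B_small values.
- The χ² limit of the within-group statistic holds as the number of
  *subjects* grows (strata in CMH theory); at n = 200, t = 5 the
  empirical law over 10⁴ margin-conditional resamples is within
  Kolmogorov distance 0.02 of χ²₈. At small n the exact permutation
  machinery — not the χ² law — carries the inference, which is the point
  of the method.

## Known limitations

- T is undefined whenever either group's statistic vanishes; very sparse
  genes in tiny groups are reported as untestable rather than tested.
- The test is sensitive to differences in the *intensity* of partial
  association, not its direction; alternatives where case and control
  patterns differ but have equal GCMH magnitude are invisible to T.
- Covariate adjustment beyond the per-subject stratification (each
  subject's table is compared to its own conditional expectation) is not
  implemented; group-level stratified analysis is out of scope.
- BH multiple-testing adjustment is available but off by default;
  permutation p-values have resolution 1/(B+1).
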