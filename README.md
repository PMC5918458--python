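# exat — exact gene-level association testing for small sequencing studies

Burden and variance-component tests (SKAT and relatives) for gene-level
rare-variant association rely on large-sample asymptotics. Targeted
sequencing studies often have a few dozen subjects, where those
approximations break down. `exat` implements an **exact association test**
built on conditional (hypergeometric) inference, aimed at exactly this
regime: tens of subjects, genes with anywhere from one to a few hundred
SNVs, common and rare alleles alike.

## The statistic

For a gene with *t* SNVs, each subject *i* contributes one stratum: a
*t* × 3 contingency table whose rows are SNVs and whose columns are the
minor-allele count *k* ∈ {0, 1, 2}, with cell n<sub>ijk</sub> = 1 iff
subject *i* carries *k* minor alleles at SNV *j*. All row margins equal 1,
so conditional on the margins the table follows the multiple
hypergeometric law

P(**n**<sub>i</sub> | H₀) = n<sub>i·0</sub>! n<sub>i·1</sub>! n<sub>i·2</sub>! / ( t! ∏<sub>s</sub> n<sub>is0</sub>! n<sub>is1</sub>! n<sub>is2</sub>! ).

The generalized Cochran–Mantel–Haenszel (GCMH) statistic pools the
per-stratum deviations from their exact conditional moments,

GCMH = **G**ᵀ Var(**G** | H₀)⁺ **G**,  **G** = Σ<sub>i</sub> A(**n**<sub>i</sub> − **m**<sub>i</sub>),

where **m**<sub>i</sub> = t·(P<sub>row</sub> ⊗ P<sub>col</sub>),
Var(**n**<sub>i</sub>|H₀) = t²/(t−1) · (D<sub>P_row</sub> − P<sub>row</sub>P<sub>row</sub>ᵀ) ⊗ (D<sub>P_col</sub> − P<sub>col</sub>P<sub>col</sub>ᵀ),
and A = (I<sub>t−1</sub> | 0) ⊗ (I₂ | 0) drops the redundant last row and
column; the degrees of freedom are 2(t−1). GCMH measures the intensity of
partial association between SNVs and minor-allele counts within a group.
The test statistic is the log ratio of the group statistics

T = log CMH<sub>case</sub> − log CMH<sub>control</sub>,

which deviates from 0 when cases and controls show differing association
patterns. Significance comes from case/control **label permutation**
(two-sided in |T|, finite-sample valid), or from a **normal-approximation
shortcut**: the permutation null of T is close to Gaussian, so its first
two moments are estimated from as few as 20 permutations and the fitted
normal is used as the approximate null law of T — at a fraction of the
cost. Genes with a single SNV fall back to an exact 2 × 3 Fisher test of
group × genotype.

## Worked example

```python
from exat import generate_ipmn_like_fixture, analyze_all

matrix, labels, gene_map = generate_ipmn_like_fixture(
    seed=11, n_subjects=44, n_case=21, n_genes=12, assoc_fraction=0.25
)
results = analyze_all(matrix, gene_map, method="permutation", B=10_000, seed=0)
print(results.round(3).to_string(index=False))
```

```
 gene_id   t  cmh_case  cmh_control      T  p_value       method     B flags
GENE0000  15   107.155      101.776  0.052    0.840  permutation 10000
GENE0001  51   337.421      426.634 -0.235    0.067  permutation 10000
GENE0002  45   277.232      260.973  0.060    0.737  permutation 10000
GENE0003   9    74.540       26.598  1.031    0.015  permutation 10000
GENE0004  11    97.102      140.782 -0.371    0.172  permutation 10000
GENE0005   1       NaN          NaN    NaN    1.000 fisher_exact     0
GENE0006  25   147.501      127.361  0.147    0.486  permutation 10000
GENE0007 120   673.088      728.064 -0.079    0.508  permutation 10000
GENE0008  29   250.270      182.732  0.315    0.101  permutation 10000
GENE0009   3    28.533        4.000  1.965    0.006  permutation 10000
GENE0010  61   418.106      421.509 -0.008    0.966  permutation 10000
GENE0011  14   126.199       86.515  0.378    0.313  permutation 10000
```

Each row is one gene: `t` is its SNV count, `cmh_case`/`cmh_control` the
group GCMH statistics, `T` their log ratio, and `p_value` the two-sided
permutation p-value over 10,000 label permutations. Here GENE0003 and
GENE0009 (both simulated as truly associated: cases carry a hot-spot
pattern of common SNVs that controls lack) reach p ≤ 0.05; the
single-SNV GENE0005 was routed to the exact Fisher test.

The same analysis is available as a scikit-learn style estimator that
composes with pipelines and selects the variants of significant genes:

```python
from exat import ExactAssociationTest
est = ExactAssociationTest(gene_map=gene_map, method="permutation",
                           B=10_000, alpha=0.05, random_state=0)
est.fit(matrix.counts, labels)
est.significant_genes()     # ['GENE0003', 'GENE0009']
```

and as a command line:

```bash
exat run --matrix geno.tsv --labels labels.tsv --genes genes.tsv \
         --method perm --B 10000 --seed 0 --out results.tsv
exat simulate-null --n 50 --replicates 1000 --seed 0 --out type1.tsv
exat diagnose-approx --matrix geno.tsv --labels labels.tsv \
         --genes genes.tsv --out panel.tsv
```

Inputs are a VCF (`--vcf`) or a TSV genotype matrix of minor-allele
counts, a two-column subject→label TSV, and a gene map (two-column TSV or
BED intervals).

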