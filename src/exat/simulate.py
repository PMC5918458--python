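"""Synthetic genotype/phenotype generation and the type-I-error study.

The null-simulation design mirrors a small-sample targeted-sequencing
study: a 5-kb variant region, a Beta site-frequency spectrum biased
toward rare alleles, Hardy-Weinberg genotypes (optionally with first-order
haplotype LD through a Gaussian-copula AR(1) chain), and a dichotomous
phenotype assigned by random permutation independently of the genotypes —
so every rejection is a type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import normal_approx_pvalue, permutation_pvalue
from .tables import GeneMap, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "generate_null_dataset",
    "type1_error_study",
    "generate_ipmn_like_fixture",
]


@dataclass
class SimulationConfig:
    """Design of the null type-I-error study.

    Defaults encode the study conditions: balanced case/control labels,
    5-kb regions, a rare-biased Beta(0.3, 3) MAF spectrum truncated to
    [1/(2n), 0.5], independent variants, and alpha levels 0.05/0.01/0.001.
    ``variant_density`` of 0.003 per bp gives on average 15 variants per
    5-kb region (the median gene size of the motivating targeted panel).
    """

    n_subjects: int = 50
    case_fraction: float = 0.5
    region_length_bp: int = 5000
    variant_density: float = 0.003
    n_variants: int | None = None  # fixed t overrides the Poisson draw
    maf_beta: tuple = (0.3, 3.0)
    ld_model: str = "independent"  # or "markov"
    ld_rho: float = 0.0
    n_replicates: int = 1000
    alpha_levels: tuple = (0.05, 0.01, 0.001)
    method: str = "normal_approx"  # or "permutation"
    B: int = 10_000
    B_small: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if any(not 0.0 < a <= 1.0 for a in self.alpha_levels):
            raise ValueError("alpha levels must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ld_model not in ("independent", "markov"):
            raise ValueError("ld_model must be 'independent' or 'markov'")


def _draw_mafs(t: int, n_subjects: int, beta_ab: tuple, rng: np.random.Generator) -> np.ndarray:
    """Beta MAF spectrum truncated to [1/(2n), 0.5] by rejection."""
    lo, hi = 1.0 / (2 * n_subjects), 0.5
    out = np.empty(t)
    filled = 0
    while filled < t:
        draw = rng.beta(*beta_ab, size=2 * (t - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)][: t - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _draw_genotypes(mafs, n, ld_model, rho, rng):
    t = mafs.size
    if ld_model == "independent" or rho == 0.0:
        return rng.binomial(2, mafs, size=(n, t)).astype(np.int8)
    # Gaussian-copula AR(1) chain per haplotype: adjacent sites share a
    # latent correlation rho; marginals stay Bernoulli(maf).
    thresh = norm.ppf(mafs)
    geno = np.zeros((n, t), dtype=np.int8)
    for _ in range(2):
        z = np.empty((n, t))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, t - 1))
        for j in range(1, t):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho * rho) * eps[:, j - 1]
        geno += (z < thresh).astype(np.int8)
    return geno


def _balanced_labels(n, case_fraction, rng):
    n_case = int(round(n * case_fraction))
    lab = np.zeros(n, dtype=np.int8)
    lab[:n_case] = 1
    return rng.permutation(lab)


def generate_null_dataset(config: SimulationConfig, replicate_seed=None):
    """One null dataset: genotypes for a 5-kb-like region + random labels.

    Variants monomorphic in the sample are removed; a draw leaving fewer
    than 2 polymorphic variants is resampled (retry cap 10, then error).
    Labels are assigned by permutation independently of the genotypes, so
    the null hypothesis holds by construction.
    """
    rng = np.random.default_rng(replicate_seed if replicate_seed is not None else config.seed)
    n = config.n_subjects
    for _ in range(10):
        if config.n_variants is not None:
            t = config.n_variants
        else:
            t = int(rng.poisson(config.region_length_bp * config.variant_density))
        if t < 2:
            continue
        mafs = _draw_mafs(t, n, config.maf_beta, rng)
        geno = _draw_genotypes(mafs, n, config.ld_model, config.ld_rho, rng)
        poly = np.ptp(geno, axis=0) > 0
        geno = geno[:, poly]
        if geno.shape[1] >= 2:
            labels = _balanced_labels(n, config.case_fraction, rng)
            t_eff = geno.shape[1]
            matrix = GenotypeMatrix(
                subject_ids=[f"S{i}" for i in range(n)],
                variant_ids=[f"v{j}" for j in range(t_eff)],
                counts=geno,
                labels=labels,
            )
            return matrix, labels
    raise RuntimeError("could not draw a polymorphic region in 10 attempts")


def type1_error_study(config: SimulationConfig) -> pd.DataFrame:
    """Empirical type-I-error table for the configured null design.

    For each replicate a fresh null dataset is generated and a single
    EXAT p-value computed for the whole region; the table reports, per
    alpha level, the rejection proportion, its binomial Monte-Carlo
    standard error and the effective number of replicates. Replicates
    with an untestable region (undefined observed T) are excluded from
    the denominator and counted. Fully reproducible from ``config.seed``.
    """
    pvals = np.full(config.n_replicates, np.nan)
    n_excluded = 0
    for r in range(config.n_replicates):
        ss = np.random.SeedSequence([int(config.seed), r])
        matrix, _ = generate_null_dataset(config, replicate_seed=ss)
        ss_test = np.random.SeedSequence([int(config.seed), r, 1])
        if config.method == "normal_approx":
            res = normal_approx_pvalue(matrix, matrix.variant_ids,
                                       B_small=config.B_small, seed=ss_test)
        else:
            res, _ = permutation_pvalue(matrix, matrix.variant_ids,
                                        B=config.B, seed=ss_test)
        if np.isnan(res.p_value):
            n_excluded += 1
        else:
            pvals[r] = res.p_value
    ok = ~np.isnan(pvals)
    n_eff = int(ok.sum())
    rows = []
    for alpha in config.alpha_levels:
        rate = float(np.mean(pvals[ok] <= alpha)) if n_eff else np.nan
        se = float(np.sqrt(rate * (1 - rate) / n_eff)) if n_eff else np.nan
        rows.append({
            "n_subjects": config.n_subjects, "alpha": alpha, "rate": rate,
            "se": se, "n_replicates": n_eff, "n_excluded": n_excluded,
        })
    return pd.DataFrame(rows)


def generate_ipmn_like_fixture(
    seed=0,
    n_subjects: int = 44,
    n_case: int = 21,
    n_genes: int = 411,
    assoc_fraction: float = 0.0,
    effect_maf: float = 0.45,
):
    """A study-shaped synthetic fixture: tens of subjects, hundreds of genes.

    Gene sizes are drawn log-normally (median 15 SNVs, clipped to 1..188,
    matching the shape of a targeted cancer panel), with at least one
    single-SNV gene (exercising the Fisher fallback) and one large gene
    (t >= 100) guaranteed. The default split is 21 cases / 23 controls.
    With ``assoc_fraction > 0`` that share of genes is made non-null by
    raising the case-group MAF of a random third of their SNVs to
    ``effect_maf``: cases then show a hot-spot partial-association
    pattern (a few common SNVs among mostly rare ones) that controls
    lack, which is exactly the differential-intensity alternative the
    log-ratio statistic targets.

    Returns ``(GenotypeMatrix, labels, GeneMap)``.
    """
    rng = np.random.default_rng(seed)
    sizes = np.clip(np.rint(rng.lognormal(np.log(15.0), 0.9, size=n_genes)), 1, 188).astype(int)
    if not (sizes == 1).any():
        sizes[int(rng.integers(n_genes))] = 1
    if not (sizes >= 100).any():
        sizes[int(rng.integers(n_genes))] = 120
    labels = np.zeros(n_subjects, dtype=np.int8)
    labels[:n_case] = 1
    labels = rng.permutation(labels)
    is_case = labels == 1

    assoc = rng.random(n_genes) < assoc_fraction
    gene_map = GeneMap()
    blocks = []
    variant_ids = []
    for g in range(n_genes):
        t = int(sizes[g])
        gid = f"GENE{g:04d}"
        vids = [f"{gid}:snv{j}" for j in range(t)]
        mafs = _draw_mafs(t, n_subjects, (0.3, 3.0), rng)
        geno = rng.binomial(2, mafs, size=(n_subjects, t)).astype(np.int8)
        if assoc[g] and t >= 2:
            hit = rng.random(t) < 1 / 3
            if not hit.any():
                hit[int(rng.integers(t))] = True
            geno_case = rng.binomial(
                2, np.where(hit, effect_maf, mafs), size=(int(is_case.sum()), t)
            ).astype(np.int8)
            geno[is_case] = geno_case
        blocks.append(geno)
        variant_ids.extend(vids)
        gene_map[gid] = vids
    counts = np.hstack(blocks)
    matrix = GenotypeMatrix(
        subject_ids=[f"S{i:03d}" for i in range(n_subjects)],
        variant_ids=variant_ids,
        counts=counts,
        labels=labels,
    )
    return matrix, labels, gene_map
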