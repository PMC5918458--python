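"""Independent brute-force reference implementations (test-only).

Deliberately slow and simple, sharing no code with the optimized paths in
``src/``: the multiple hypergeometric null of one subject's table is
enumerated term by term from the printed probability formula, and exact
permutation p-values iterate every label partition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from exat.tables import GenotypeMatrix

ENUM_T_CAP = 10
LABEL_SUBJECT_CAP = 12


@dataclass
class EnumeratedNull:
    tables: list          # list of (t, 3) integer arrays
    probabilities: list   # matching probabilities, summing to 1
    mean: np.ndarray      # exact mean of the row-major vectorized table
    cov: np.ndarray       # exact covariance (3t x 3t)


def _table_probability(table: np.ndarray) -> float:
    """Multiple hypergeometric probability of a t x 3 table, all margins fixed.

    P(n_i | H0) = n_.0! n_.1! n_.2! / (t! * prod_s n_s0! n_s1! n_s2!).
    """
    t = table.shape[0]
    col = table.sum(axis=0)
    num = math.factorial(col[0]) * math.factorial(col[1]) * math.factorial(col[2])
    den = math.factorial(t)
    for s in range(t):
        for k in range(3):
            den *= math.factorial(int(table[s, k]))
    return num / den


def enumerate_subject_null(col_margins) -> EnumeratedNull:
    """All tables with row margins 1 and the given column margins.

    Enumerates the distinct assignments of column labels to the t rows;
    each table's probability comes from the hypergeometric formula (they
    are equal across arrangements and sum to 1). Exact moments by
    weighted sums. Refuses t above a small cap (test-only code).
    """
    k0, k1, k2 = (int(c) for c in col_margins)
    t = k0 + k1 + k2
    if t > ENUM_T_CAP:
        raise ValueError(f"enumeration capped at t = {ENUM_T_CAP}")
    if t < 1 or min(k0, k1, k2) < 0:
        raise ValueError("column margins must be non-negative with t >= 1")
    labels = (0,) * k0 + (1,) * k1 + (2,) * k2
    arrangements = sorted(set(itertools.permutations(labels)))
    tables, probs, vecs = [], [], []
    for arr in arrangements:
        tab = np.zeros((t, 3), dtype=np.int64)
        tab[np.arange(t), list(arr)] = 1
        tables.append(tab)
        probs.append(_table_probability(tab))
        vecs.append(tab.reshape(-1).astype(float))
    probs_arr = np.array(probs)
    assert abs(probs_arr.sum() - 1.0) < 1e-12
    vecs_arr = np.array(vecs)
    mean = probs_arr @ vecs_arr
    centered = vecs_arr - mean
    cov = (centered * probs_arr[:, None]).T @ centered
    return EnumeratedNull(tables=tables, probabilities=list(probs_arr), mean=mean, cov=cov)


def oracle_gcmh(genotype_rows) -> float:
    """GCMH by explicit enumeration-based moments and a full quadratic form.

    Moments per subject come from :func:`enumerate_subject_null` (not the
    analytical formulas); the reduction matrix is built by explicit index
    bookkeeping and the covariance is pseudo-inverted with numpy defaults.
    """
    rows = [np.asarray(g, dtype=int) for g in genotype_rows]
    t = rows[0].size
    # reduction: keep cells (j, k) with j < t-1, k < 2, in row-major order
    keep = [3 * j + k for j in range(t - 1) for k in range(2)]
    G = np.zeros(len(keep))
    V = np.zeros((len(keep), len(keep)))
    for g in rows:
        margins = [int(np.sum(g == k)) for k in (0, 1, 2)]
        null = enumerate_subject_null(margins)
        tab = np.zeros((t, 3), dtype=np.int64)
        tab[np.arange(t), g] = 1
        vec = tab.reshape(-1).astype(float)
        G += (vec - null.mean)[keep]
        V += null.cov[np.ix_(keep, keep)]
    return float(G @ np.linalg.pinv(V, hermitian=True) @ G)


def oracle_T(geno: np.ndarray, labels: np.ndarray) -> float:
    """Log-ratio statistic via the enumeration-based GCMH (NaN if undefined)."""
    geno = np.asarray(geno)
    labels = np.asarray(labels)
    c1 = oracle_gcmh(geno[labels == 1])
    c0 = oracle_gcmh(geno[labels == 0])
    if c1 <= 1e-12 or c0 <= 1e-12:
        return float("nan")
    return math.log(c1) - math.log(c0)


def exhaustive_label_pvalue(matrix_or_geno, labels=None):
    """Exact two-sided p over all label partitions of the observed sizes.

    p = proportion of partitions with a defined T_b and |T_b| >= |T_obs|
    among all defined partitions (the observed partition is included, so
    p > 0). Refuses more than 12 subjects.
    """
    if isinstance(matrix_or_geno, GenotypeMatrix):
        geno = matrix_or_geno.counts
        labels = matrix_or_geno.labels
    else:
        geno = np.asarray(matrix_or_geno)
        labels = np.asarray(labels)
    n = geno.shape[0]
    if n > LABEL_SUBJECT_CAP:
        raise ValueError(f"exhaustive enumeration capped at {LABEL_SUBJECT_CAP} subjects")
    n_case = int(np.sum(labels == 1))
    T_obs = oracle_T(geno, labels)
    if math.isnan(T_obs):
        raise ValueError("observed T undefined; no exact p")
    count = 0
    n_def = 0
    for case_idx in itertools.combinations(range(n), n_case):
        lab = np.zeros(n, dtype=int)
        lab[list(case_idx)] = 1
        T_b = oracle_T(geno, lab)
        if math.isnan(T_b):
            continue
        n_def += 1
        if abs(T_b) >= abs(T_obs) - 1e-12:
            count += 1
    return count / n_def
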