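"""Generalized Cochran-Mantel-Haenszel statistic for stacks of t x 3 tables.

Each subject contributes one stratum: a t x 3 table whose rows are SNVs and
whose columns are minor-allele counts, with all row margins equal to 1.
Conditional on all margins, the table follows the multiple hypergeometric
law, which here reduces to a uniform distribution over the arrangements of
the column labels across rows. The general-association GCMH statistic is
the quadratic form

    GCMH = G' Var(G | H0)^+ G,      G = sum_i A (n_i - m_i),

where n_i is the row-major vectorized table, m_i its exact null mean,
A = (I_{t-1} | 0) ⊗ (I_2 | 0) drops the redundant last SNV row and the
k = 2 column, and the null covariance of n_i factorizes as a Kronecker
product of a row factor and a column factor. Under H0 the statistic is
asymptotically chi-squared with 2(t - 1) degrees of freedom as the number
of subjects grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables import SubjectTable

__all__ = [
    "TableMoments",
    "GcmhResult",
    "table_moments",
    "reduction_matrix",
    "gcmh_statistic",
    "PINV_RTOL",
]

# singular values below PINV_RTOL * sigma_max are treated as zero when the
# pooled covariance is (pseudo-)inverted
PINV_RTOL = 1e-10


@dataclass
class TableMoments:
    """Exact null mean and covariance of one subject's vectorized table."""

    P_row: np.ndarray  # length t, all 1/t (row margins are fixed at 1)
    P_col: np.ndarray  # length 3, column margins / t
    m: np.ndarray      # length 3t expected counts, row-major (j, k) order
    V: np.ndarray      # 3t x 3t null covariance


@dataclass
class GcmhResult:
    statistic: float
    df: int
    G: np.ndarray
    VarG: np.ndarray
    rank: int
    degenerate: bool


def table_moments(table: SubjectTable) -> TableMoments:
    """Exact null moments of the vectorized table, all margins fixed.

    Mean is ``t * (P_row ⊗ P_col)`` and covariance is
    ``t^2/(t-1) * (D_Prow - Prow Prow') ⊗ (D_Pcol - Pcol Pcol')`` in the
    row-major (SNV-major) vectorization ``(n_{i10}, n_{i11}, n_{i12},
    n_{i20}, ...)``.
    """
    t = table.t
    if t < 2:
        raise ValueError("moments are undefined for t = 1 (t - 1 in the denominator)")
    p_row = np.full(t, 1.0 / t)
    p_col = table.col_margins / t
    m = t * np.kron(p_row, p_col)
    row_factor = np.diag(p_row) - np.outer(p_row, p_row)
    col_factor = np.diag(p_col) - np.outer(p_col, p_col)
    V = (t * t / (t - 1.0)) * np.kron(row_factor, col_factor)
    return TableMoments(P_row=p_row, P_col=p_col, m=m, V=V)


def reduction_matrix(t: int) -> np.ndarray:
    """The 2(t-1) x 3t matrix ``(I_{t-1} | 0) ⊗ (I_2 | 0)``.

    Applied to a row-major vectorized table it drops the last SNV row and
    the k = 2 genotype column, leaving the 2(t-1) free cells.
    """
    if t < 2:
        raise ValueError("reduction matrix requires t >= 2")
    row_part = np.hstack([np.eye(t - 1), np.zeros((t - 1, 1))])
    col_part = np.hstack([np.eye(2), np.zeros((2, 1))])
    return np.kron(row_part, col_part)


def gcmh_statistic(tables: Sequence[SubjectTable]) -> GcmhResult:
    """Pooled GCMH statistic over one group's subject tables.

    Subjects are independent strata: ``G`` and ``Var(G|H0)`` are summed
    over subjects and only the pooled covariance is inverted, via a
    Moore-Penrose pseudo-inverse (rank deficiency is generic when variants
    are monomorphic or allele diversity is low; the ``degenerate`` flag
    records it).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("at least one subject table is required")
    t = tables[0].t
    if any(tab.t != t for tab in tables):
        raise ValueError("all subject tables must share the same number of SNVs")
    if t < 2:
        raise ValueError("GCMH requires t >= 2 SNVs")
    A = reduction_matrix(t)
    df = 2 * (t - 1)
    G = np.zeros(df)
    VarG = np.zeros((df, df))
    for tab in tables:
        mom = table_moments(tab)
        n_vec = tab.counts.reshape(-1).astype(float)
        G += A @ (n_vec - mom.m)
        VarG += A @ mom.V @ A.T

    s = np.linalg.svd(VarG, compute_uv=False, hermitian=True)
    rank = int(np.sum(s > PINV_RTOL * (s[0] if s.size else 0.0)))
    pinv = np.linalg.pinv(VarG, hermitian=True, rtol=PINV_RTOL)
    statistic = float(G @ pinv @ G)
    statistic = max(statistic, 0.0)
    degenerate = rank < df or not np.any(G)
    return GcmhResult(statistic=statistic, df=df, G=G, VarG=VarG, rank=rank, degenerate=degenerate)
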