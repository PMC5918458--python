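"""Vectorized GCMH evaluation over many label assignments.

The pooled reduced covariance of one group factorizes as a Kronecker
product, ``Var(G|H0) = t^2/(t-1) * R ⊗ sum_i C_i`` with
``R = I/t - J/t^2`` of order t-1 (a full-rank matrix whose inverse is
``t (I + J)``) and ``C_i`` the subject's reduced 2 x 2 column factor.
Hence

    GCMH = (t-1)/t * [ tr(M' M C+) + s' C+ s ],

where ``M`` is the (t-1) x 2 matrix of summed centered cell counts for
the group, ``s`` its column sums and ``C+`` the pseudo-inverse of the
summed column factor. Only 2 x 2 pseudo-inverses are needed per label
assignment, so thousands of permutations evaluate as a handful of BLAS
calls. Equality with the plain matrix path in :mod:`exat.gcmh` is pinned
by the test suite.
"""

from __future__ import annotations

import numpy as np

from .gcmh import PINV_RTOL

__all__ = ["gene_precompute", "group_statistics", "permutation_masks"]


def gene_precompute(geno: np.ndarray):
    """Per-subject reduced centered tables and column factors for one gene.

    Parameters
    ----------
    geno
        ``(n, t)`` genotype submatrix for the gene, entries in {0, 1, 2},
        no missing values, ``t >= 2``.

    Returns
    -------
    D : ``(n, 2(t-1))`` row-major flattened ``A (n_i - m_i)`` per subject.
    C : ``(n, 2, 2)`` reduced column factors ``D_pcol - pcol pcol'``.
    """
    geno = np.asarray(geno)
    n, t = geno.shape
    if t < 2:
        raise ValueError("kernel requires t >= 2")
    ind = np.zeros((n, t, 3))
    ind[np.arange(n)[:, None], np.arange(t)[None, :], geno.astype(int)] = 1.0
    p = ind.sum(axis=1) / t                       # (n, 3) column margins / t
    D = (ind - p[:, None, :])[:, : t - 1, :2].reshape(n, 2 * (t - 1))
    p0, p1 = p[:, 0], p[:, 1]
    C = np.empty((n, 2, 2))
    C[:, 0, 0] = p0 * (1.0 - p0)
    C[:, 1, 1] = p1 * (1.0 - p1)
    C[:, 0, 1] = C[:, 1, 0] = -p0 * p1
    return D, C


def group_statistics(D: np.ndarray, C: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """GCMH statistic of the subjects selected by each mask row.

    ``masks`` is ``(B, n)`` boolean/0-1; each row defines one group. The
    summed column factor is pseudo-inverted per mask (rank deficiency is
    legitimate and common: e.g. a group carrying only {0, 1} genotypes has
    a rank-1 factor).
    """
    masks = np.asarray(masks, dtype=float)
    B = masks.shape[0]
    two_tm1 = D.shape[1]
    t = two_tm1 // 2 + 1
    M = (masks @ D).reshape(B, t - 1, 2)
    Csum = np.einsum("bn,nij->bij", masks, C)
    Cp = np.linalg.pinv(Csum, hermitian=True, rtol=PINV_RTOL)
    MtM = np.einsum("bji,bjk->bik", M, M)
    s = M.sum(axis=1)
    quad = np.einsum("bik,bki->b", MtM, Cp) + np.einsum("bi,bik,bk->b", s, Cp, s)
    return np.maximum((t - 1.0) / t * quad, 0.0)


def permutation_masks(labels: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """``(B, n)`` case masks from uniform label permutations (sizes preserved)."""
    lab = np.tile(np.asarray(labels, dtype=bool), (B, 1))
    return rng.permuted(lab, axis=1)
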