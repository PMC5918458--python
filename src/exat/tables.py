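"""Genotype containers and per-subject contingency-table construction.

The exact association test views a gene with ``t`` SNVs as a stack of
per-subject t x 3 contingency tables: rows are SNVs, columns are the
minor-allele count (0, 1 or 2), and every cell is an indicator, so each
row margin is 1 and the table total is ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GeneMap",
    "SubjectTable",
    "GeneTables",
    "build_subject_table",
    "build_gene_tables",
    "MISSING_POLICIES",
]

MISSING_POLICIES = ("fail", "drop_variant", "drop_subject")


@dataclass
class GenotypeMatrix:
    """Subjects x variants minor-allele counts with a binary phenotype.

    Parameters
    ----------
    subject_ids, variant_ids
        Unique identifiers for rows and columns of ``counts``.
    counts
        ``(n_subjects, n_variants)`` integer matrix with entries in
        ``{0, 1, 2}`` (number of minor alleles carried).
    labels
        Per-subject phenotype, 1 = case, 0 = control.
    missing_mask
        Optional boolean matrix, ``True`` where the genotype call is
        missing; masked entries of ``counts`` are ignored.
    positions
        Optional per-variant ``(chrom, pos)`` pairs (1-based positions),
        used for BED-interval gene maps and deterministic ordering.
    """

    subject_ids: list
    variant_ids: list
    counts: np.ndarray
    labels: np.ndarray
    missing_mask: np.ndarray | None = None
    positions: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.subject_ids = list(self.subject_ids)
        self.variant_ids = list(self.variant_ids)
        n, m = self.counts.shape
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got {n}")
        if len(self.subject_ids) != n or len(self.variant_ids) != m:
            raise ValueError("identifier lists do not match the counts shape")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids are not unique")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant_ids are not unique")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per subject")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = control, 1 = case)")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, m):
                raise ValueError("missing_mask shape mismatch")
        observed = self.counts if self.missing_mask is None else self.counts[~self.missing_mask]
        bad = ~np.isin(observed, (0, 1, 2))
        if bad.any():
            idx = np.argwhere(~np.isin(self.counts, (0, 1, 2)))
            if self.missing_mask is not None:
                idx = idx[~self.missing_mask[idx[:, 0], idx[:, 1]]]
            i, j = idx[0]
            raise ValueError(
                f"genotype for subject {self.subject_ids[i]!r} at variant "
                f"{self.variant_ids[j]!r} is {self.counts[i, j]}, not in {{0, 1, 2}}"
            )
        self._variant_index = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def variant_columns(self, variant_ids: Sequence) -> np.ndarray:
        """Column indices of the given variant ids (KeyError if absent)."""
        try:
            return np.array([self._variant_index[v] for v in variant_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"variant {e.args[0]!r} not present in the genotype matrix") from None

    def require_both_groups(self):
        if not (self.labels == 1).any() or not (self.labels == 0).any():
            raise ValueError("both case and control subjects are required for testing")


class GeneMap(dict):
    """Mapping gene_id -> ordered list of variant_ids.

    A thin dict subclass; :meth:`validate` checks every referenced variant
    against a :class:`GenotypeMatrix`.
    """

    def __init__(self, mapping: Mapping[str, Sequence] | None = None):
        super().__init__()
        if mapping:
            for g, vs in mapping.items():
                self[g] = list(vs)

    def validate(self, matrix: GenotypeMatrix) -> None:
        for gene, variants in self.items():
            if len(variants) < 1:
                raise ValueError(f"gene {gene!r} maps to no variants")
            matrix.variant_columns(variants)


@dataclass
class SubjectTable:
    """One subject's t x 3 SNV-by-genotype indicator table."""

    counts: np.ndarray  # (t, 3) of 0/1
    subject_id: object = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("a subject table must be t x 3")
        if not np.isin(self.counts, (0, 1)).all():
            raise ValueError("subject-table cells must be 0/1 indicators")
        if not (self.counts.sum(axis=1) == 1).all():
            raise ValueError("every SNV row must have exactly one genotype indicator")

    @property
    def t(self) -> int:
        return self.counts.shape[0]

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def genotypes(self) -> np.ndarray:
        """Recover the genotype vector (argmax over the indicator columns)."""
        return self.counts.argmax(axis=1)


def build_subject_table(genotype_row: Sequence[int], subject_id=None) -> SubjectTable:
    """Turn one subject's genotype vector into its t x 3 indicator table.

    Cell ``(j, k)`` is 1 iff the genotype at SNV ``j`` equals ``k``.
    """
    g = np.asarray(genotype_row)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("genotype_row must be a non-empty 1-D vector")
    if np.ma.is_masked(g) or (g.dtype.kind == "f" and np.isnan(g.astype(float)).any()):
        raise ValueError(f"missing genotype for subject {subject_id!r}")
    if not np.isin(g, (0, 1, 2)).all():
        j = int(np.argwhere(~np.isin(g, (0, 1, 2)))[0][0])
        raise ValueError(
            f"genotype {g[j]} for subject {subject_id!r} at SNV index {j} is not in {{0, 1, 2}}"
        )
    t = g.size
    table = np.zeros((t, 3), dtype=np.int64)
    table[np.arange(t), g.astype(int)] = 1
    return SubjectTable(table, subject_id=subject_id)


@dataclass
class GeneTables:
    """Per-subject tables for one gene, split by phenotype group."""

    gene_id: object
    t: int
    case_tables: list = field(default_factory=list)
    control_tables: list = field(default_factory=list)
    dropped_variants: list = field(default_factory=list)
    dropped_subjects: list = field(default_factory=list)
    untestable: bool = False
    reason: str = ""

    @property
    def n_case(self) -> int:
        return len(self.case_tables)

    @property
    def n_control(self) -> int:
        return len(self.control_tables)


def resolve_gene_genotypes(
    matrix: GenotypeMatrix,
    variant_ids: Sequence,
    missing_policy: str = "fail",
):
    """Extract the complete-genotype submatrix for one gene.

    Applies the missing-data policy and returns
    ``(genotypes, labels, kept_subject_idx, dropped_variants, dropped_subjects)``
    where ``genotypes`` is ``(n_kept, t_kept)`` with no missing entries.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    cols = matrix.variant_columns(variant_ids)
    geno = matrix.counts[:, cols]
    variant_ids = list(variant_ids)
    if matrix.missing_mask is None:
        miss = np.zeros(geno.shape, dtype=bool)
    else:
        miss = matrix.missing_mask[:, cols]

    dropped_variants: list = []
    dropped_subjects: list = []
    keep_sub = np.ones(matrix.n_subjects, dtype=bool)
    if miss.any():
        if missing_policy == "fail":
            i, j = np.argwhere(miss)[0]
            raise ValueError(
                f"missing genotype for subject {matrix.subject_ids[i]!r} at "
                f"variant {variant_ids[j]!r} (missing_policy='fail')"
            )
        if missing_policy == "drop_variant":
            bad = miss.any(axis=0)
            dropped_variants = [v for v, b in zip(variant_ids, bad) if b]
            geno = geno[:, ~bad]
            variant_ids = [v for v, b in zip(variant_ids, bad) if not b]
        else:  # drop_subject
            bad = miss.any(axis=1)
            dropped_subjects = [s for s, b in zip(matrix.subject_ids, bad) if b]
            keep_sub = ~bad
            geno = geno[keep_sub]
    labels = matrix.labels[keep_sub]
    return geno, labels, np.flatnonzero(keep_sub), dropped_variants, dropped_subjects, variant_ids


def build_gene_tables(
    matrix: GenotypeMatrix,
    gene_id,
    variant_ids: Sequence,
    missing_policy: str = "fail",
) -> GeneTables:
    """Build per-subject tables for one gene, split into case/control.

    Genes left with fewer than 2 variants after the missing policy are
    flagged untestable rather than raising (single-SNV genes are handled
    by the Fisher fallback at the testing layer).
    """
    geno, labels, kept, dv, ds, kept_variants = resolve_gene_genotypes(
        matrix, variant_ids, missing_policy
    )
    t = geno.shape[1]
    out = GeneTables(gene_id=gene_id, t=t, dropped_variants=dv, dropped_subjects=ds)
    if t == 0:
        out.untestable = True
        out.reason = "all variants dropped"
        return out
    if t < 2:
        out.untestable = True
        out.reason = "single SNV (Fisher fallback applies)"
    subject_ids = [matrix.subject_ids[i] for i in kept]
    for row, lab, sid in zip(geno, labels, subject_ids):
        tab = build_subject_table(row, subject_id=sid)
        (out.case_tables if lab == 1 else out.control_tables).append(tab)
    return out
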