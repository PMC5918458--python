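"""Readers and writers for the supported file dialects.

Supported inputs: a VCF (v4.x, GT field) plus a subject-label table, or a
plain TSV genotype matrix (header = variant IDs, first column = subject
ID, cells in {0, 1, 2, NA}); gene maps as two-column TSV
(gene_id, variant_id) or BED intervals matched against VCF positions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import GeneMap, GenotypeMatrix

log = logging.getLogger("exat")

__all__ = [
    "read_matrix_tsv",
    "read_labels_tsv",
    "read_vcf",
    "read_gene_map_tsv",
    "read_gene_map_bed",
    "write_matrix_tsv",
    "write_gene_map_tsv",
    "write_labels_tsv",
]

_LABEL_CODES = {"1": 1, "0": 0, "case": 1, "control": 0}


def read_labels_tsv(path) -> pd.Series:
    """Two-column TSV subject_id -> label (1/0 or case/control), no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: subject_id, label")
    labels = df[1].str.strip().str.lower().map(_LABEL_CODES)
    if labels.isna().any():
        bad = df[1][labels.isna()].iloc[0]
        raise ValueError(f"unrecognized phenotype label {bad!r} (use 1/0 or case/control)")
    return pd.Series(labels.to_numpy(dtype=np.int8), index=df[0].str.strip())


def read_matrix_tsv(path, labels: pd.Series) -> GenotypeMatrix:
    """TSV genotype matrix: header = variant IDs, first column = subject ID."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "na", ".", ""])
    missing = df.isna().to_numpy()
    counts = df.fillna(0).to_numpy()
    if not np.isin(counts[~missing], (0, 1, 2)).all():
        raise ValueError("TSV genotype cells must be 0, 1, 2 or NA")
    subject_ids = [str(s) for s in df.index]
    absent = [s for s in subject_ids if s not in labels.index]
    if absent:
        raise ValueError(f"no phenotype label for subject(s) {absent[:5]}")
    return GenotypeMatrix(
        subject_ids=subject_ids,
        variant_ids=[str(v) for v in df.columns],
        counts=counts.astype(np.int8),
        labels=labels.loc[subject_ids].to_numpy(),
        missing_mask=missing if missing.any() else None,
    )


def read_vcf(path, labels: pd.Series) -> GenotypeMatrix:
    """Read genotypes from a VCF, coding minor-allele dosage per variant.

    Multi-allelic sites are split into bi-allelic records (a genotype
    carrying a third allele is missing for that record); ``./.`` is
    missing; phasing is ignored. ALT dosage is flipped to minor-allele
    dosage whenever the pooled ALT frequency exceeds 0.5 (logged).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in labels.index]
    if absent:
        raise ValueError(f"no phenotype label for VCF sample(s) {absent[:5]}")
    cols, miss_cols, ids, positions = [], [], [], []
    for var in vcf:
        gts = var.genotypes  # [a0, a1, phased] per sample
        for ai, alt in enumerate(var.ALT, start=1):
            dose = np.zeros(len(samples), dtype=np.int8)
            miss = np.zeros(len(samples), dtype=bool)
            for s, gt in enumerate(gts):
                a = gt[:-1]
                if any(x < 0 for x in a):
                    miss[s] = True
                elif any(x not in (0, ai) for x in a):
                    miss[s] = True  # carries another ALT of a multi-allelic site
                else:
                    dose[s] = sum(x == ai for x in a)
            vid = (
                var.ID
                if var.ID not in (None, ".") and len(var.ALT) == 1
                else f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
            )
            nm = ~miss
            if nm.any() and dose[nm].sum() > nm.sum():  # ALT freq > 0.5
                dose[nm] = 2 - dose[nm]
                log.info("variant %s re-oriented to minor-allele dosage", vid)
            dose[miss] = 0
            cols.append(dose)
            miss_cols.append(miss)
            ids.append(vid)
            positions.append((var.CHROM, var.POS))
    counts = np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    missing = (
        np.column_stack(miss_cols) if miss_cols else np.zeros_like(counts, dtype=bool)
    )
    return GenotypeMatrix(
        subject_ids=samples,
        variant_ids=ids,
        counts=counts,
        labels=labels.loc[samples].to_numpy(),
        missing_mask=missing if missing.any() else None,
        positions=positions,
    )


def read_gene_map_tsv(path) -> GeneMap:
    """Two-column TSV (gene_id, variant_id); order within a gene is kept."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("gene map TSV needs two columns: gene_id, variant_id")
    gm = GeneMap()
    for gene, vid in zip(df[0].str.strip(), df[1].str.strip()):
        gm.setdefault(gene, []).append(vid)
    return gm


def read_gene_map_bed(path, matrix: GenotypeMatrix) -> GeneMap:
    """BED intervals (0-based, half-open) matched to the matrix's variants.

    The matrix must carry VCF-style 1-based positions; a variant at
    1-based position p falls in [start, end) iff start < p <= end.
    Variants within a gene are ordered by position, ties by variant id.
    """
    if matrix.positions is None:
        raise ValueError("BED gene maps require variant positions (read the matrix from VCF)")
    bed = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if bed.shape[1] < 4:
        raise ValueError("BED gene map needs 4 columns: chrom, start, end, gene_id")
    gm = GeneMap()
    chroms = np.array([c for c, _ in matrix.positions])
    pos = np.array([p for _, p in matrix.positions], dtype=int)
    vids = np.array(matrix.variant_ids, dtype=object)
    for _, row in bed.iterrows():
        chrom, start, end, gene = row[0], int(row[1]), int(row[2]), row[3]
        inside = (chroms == chrom) & (pos > start) & (pos <= end)
        if inside.any():
            order = np.lexsort((vids[inside].astype(str), pos[inside]))
            gm.setdefault(gene, []).extend(list(vids[inside][order]))
    return gm


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.counts.astype(object), index=matrix.subject_ids, columns=matrix.variant_ids
    )
    if matrix.missing_mask is not None:
        df = df.mask(pd.DataFrame(matrix.missing_mask, index=df.index, columns=df.columns), "NA")
    df.to_csv(path, sep="\t", index_label="subject_id")


def write_labels_tsv(matrix: GenotypeMatrix, path) -> None:
    pd.DataFrame({"subject_id": matrix.subject_ids, "label": matrix.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_gene_map_tsv(gene_map: GeneMap, path) -> None:
    rows = [(g, v) for g, vs in gene_map.items() for v in vs]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
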