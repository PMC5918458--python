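"""scikit-learn style front-end for the exact association test.

:class:`ExactAssociationTest` is shaped like sklearn's univariate
feature-selection estimators: ``fit(X, y)`` computes one p-value per gene
(a group of genotype columns), and ``transform`` keeps the variants of
genes significant at ``alpha``. It composes with sklearn pipelines and
cloning/model-selection machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .association import analyze_all
from .tables import GeneMap, GenotypeMatrix

__all__ = ["ExactAssociationTest"]


class ExactAssociationTest(SelectorMixin, BaseEstimator):
    """Gene-level exact association test as a feature selector.

    Parameters
    ----------
    gene_map : dict or None
        Mapping gene_id -> list of variant identifiers. Identifiers are
        matched against ``X``'s column names when ``X`` is a DataFrame,
        or interpreted as integer column indices otherwise. ``None``
        treats all columns as one region named ``"region"``.
    method : {"permutation", "normal_approx"}
        How multi-SNV gene p-values are obtained; single-SNV genes always
        use the exact Fisher 2 x 3 fallback.
    B : int
        Number of label permutations for ``method="permutation"``.
    B_small : int
        Number of permutations used to estimate the two moments for
        ``method="normal_approx"``.
    alpha : float
        Significance level used by :meth:`transform` to select variants
        belonging to significant genes.
    bh_adjust : bool
        If True, selection uses Benjamini-Hochberg adjusted p-values.
    missing_policy : {"fail", "drop_variant", "drop_subject"}
        How missing genotypes (NaN entries of ``X``) are handled.
    random_state : int
        Master seed; per-gene streams are derived by stable hashing of
        the gene id, so results are independent of gene order.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per gene: t, CMH_case, CMH_control, T, p_value, method,
        flags (and p_adj_BH when ``bh_adjust``).
    pvalues_ : ndarray
        Per-gene p-values, in ``gene_ids_`` order.
    gene_ids_ : list
        Gene identifiers in analysis order.
    """

    def __init__(
        self,
        gene_map=None,
        method="normal_approx",
        B=10_000,
        B_small=100,
        alpha=0.05,
        bh_adjust=False,
        missing_policy="fail",
        random_state=0,
    ):
        self.gene_map = gene_map
        self.method = method
        self.B = B
        self.B_small = B_small
        self.alpha = alpha
        self.bh_adjust = bh_adjust
        self.missing_policy = missing_policy
        self.random_state = random_state

    def fit(self, X, y):
        """Run the test on a subjects x variants matrix and binary labels."""
        if isinstance(X, pd.DataFrame):
            variant_ids = [str(c) for c in X.columns]
            subject_ids = [str(s) for s in X.index]
            values = X.to_numpy()
            self.feature_names_in_ = np.asarray(variant_ids, dtype=object)
        else:
            values = np.asarray(X)
            variant_ids = [f"v{j}" for j in range(values.shape[1])]
            subject_ids = [f"s{i}" for i in range(values.shape[0])]
        y = np.asarray(y)
        values = np.asarray(values, dtype=float)
        missing = np.isnan(values)
        matrix = GenotypeMatrix(
            subject_ids=subject_ids,
            variant_ids=variant_ids,
            counts=np.where(missing, 0, values).astype(np.int8),
            labels=y,
            missing_mask=missing if missing.any() else None,
        )
        matrix.require_both_groups()
        if self.gene_map is None:
            gm = GeneMap({"region": variant_ids})
        else:
            gm = GeneMap({
                g: [variant_ids[v] if isinstance(v, (int, np.integer)) else str(v)
                    for v in vs]
                for g, vs in self.gene_map.items()
            })
        gm.validate(matrix)
        self.results_ = analyze_all(
            matrix, gm, method=self.method, B=self.B, B_small=self.B_small,
            seed=self.random_state, missing_policy=self.missing_policy,
            bh_adjust=self.bh_adjust,
        )
        self.gene_ids_ = list(self.results_["gene_id"])
        self.pvalues_ = self.results_["p_value"].to_numpy()
        self.n_features_in_ = len(variant_ids)
        pcol = "p_adj_BH" if self.bh_adjust else "p_value"
        sig = set(self.results_.loc[self.results_[pcol] <= self.alpha, "gene_id"])
        mask = np.zeros(self.n_features_in_, dtype=bool)
        vindex = {v: j for j, v in enumerate(variant_ids)}
        for g in sig:
            for v in gm[g]:
                mask[vindex[v]] = True
        self.support_mask_ = mask
        self.gene_map_ = gm
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def significant_genes(self):
        """Gene ids significant at ``alpha`` (BH-adjusted if configured)."""
        check_is_fitted(self, "results_")
        pcol = "p_adj_BH" if self.bh_adjust else "p_value"
        return list(self.results_.loc[self.results_[pcol] <= self.alpha, "gene_id"])
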