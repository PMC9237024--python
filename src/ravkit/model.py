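"""The RAV model as a scikit-learn style estimator.

:class:`RAVModel` is fit on a list of per-study expression matrices
(building the index of replicable axes of variation) and afterwards acts
as a transformer: ``transform`` maps a new dataset to its samples x RAVs
score matrix. Annotation (gene sets, MeSH) and interpretation helpers
hang off the fitted estimator.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import annotate as _annotate
from . import apply as _apply
from . import rav_build
from .containers import ExpressionMatrix

__all__ = ["RAVModel"]


class RAVModel(BaseEstimator, TransformerMixin):
    """Index of replicable axes of variation learned from many studies.

    Parameters
    ----------
    n_pcs : int, default 20
        Loading vectors kept per study (ordered by variance explained).
    d : float, default 2.25
        Cluster-count divisor; the tree is cut at round(total PCs / d)
        clusters. 2.25 is the value at which synthetic negative controls
        separate into singletons in the full-scale calibration.
    variance_quantile : float, default 0.90
        Per-study top-variable-gene fraction retained before intersecting
        gene lists across studies.
    n_clusters : int or None
        Explicit cluster count overriding the d rule.

    Attributes (after ``fit``)
    --------------------------
    rav_index_ : RAVIndex
        Genes x RAVs averaged loadings plus per-cluster bookkeeping.
    stats_ : NormalizationStats
        Pooled per-gene mean/sd used for row normalisation.
    genes_ : pd.Index
        The common genes the model operates on.
    assignment_, pooled_ : clustering inputs kept for provenance.
    gsea_, mesh_ : annotation tables, set by the annotate methods.
    """

    def __init__(
        self,
        n_pcs: int = 20,
        d: float = 2.25,
        variance_quantile: float = 0.90,
        n_clusters: int | None = None,
    ):
        self.n_pcs = n_pcs
        self.d = d
        self.variance_quantile = variance_quantile
        self.n_clusters = n_clusters

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        X: Sequence[ExpressionMatrix],
        y=None,
        controls: Sequence[ExpressionMatrix] | None = None,
        study_meta: pd.DataFrame | None = None,
    ) -> "RAVModel":
        """Build the RAV index from per-study log-scale matrices.

        ``controls`` are pre-normalised negative-control matrices whose
        PC1s join the pool flagged as controls. ``study_meta`` (indexed by
        study id, e.g. with ``title`` and ``meshTerms`` columns) is kept
        for lookups and MeSH annotation.
        """
        result = rav_build.build_rav_index(
            list(X),
            n_pcs=self.n_pcs,
            d=self.d,
            variance_quantile=self.variance_quantile,
            n_clusters=self.n_clusters,
            controls=controls,
        )
        self.rav_index_ = result.index
        self.stats_ = result.stats
        self.genes_ = result.genes
        self.assignment_ = result.assignment
        self.pooled_ = result.pooled
        self.dropped_genes_ = result.dropped_genes
        self.study_meta_ = study_meta
        self.n_pooled_ = result.pooled.n_columns
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "rav_index_"):
            raise NotFittedError("RAVModel is not fitted; call fit first")

    @property
    def rav_ids(self) -> list[str]:
        self._check_fitted()
        return list(self.rav_index_.ravs.columns)

    # -- application ------------------------------------------------------

    def transform(self, X: ExpressionMatrix, rav_ids=None, min_genes: int = 1000) -> pd.DataFrame:
        """Samples x RAVs score matrix for a new dataset."""
        self._check_fitted()
        return _apply.sample_scores(X, self, rav_ids=rav_ids, min_genes=min_genes)

    def validate(self, X: ExpressionMatrix, n_pc: int = 8, min_genes: int = 1000):
        """Validation scores of every RAV against a new dataset."""
        self._check_fitted()
        return _apply.validate(X, self, n_pc=n_pc, min_genes=min_genes)

    def meta_association(self, scores: pd.DataFrame, variable):
        return _apply.meta_association_r2(scores, variable)

    # -- annotation -------------------------------------------------------

    def annotate_gsea(self, coll, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05, keep: str = "min_q"):
        self._check_fitted()
        return _annotate.annotate_gsea(self, coll, n_perm=n_perm, seed=seed, alpha=alpha, keep=keep)

    def annotate_mesh(self, study_terms: Mapping[str, Sequence[str]] | None = None, **kwargs):
        self._check_fitted()
        if study_terms is None:
            if self.study_meta_ is None or "meshTerms" not in self.study_meta_.columns:
                raise ValueError("no study MeSH metadata available")
            study_terms = self.study_meta_["meshTerms"].to_dict()
        return _annotate.annotate_mesh(self, study_terms, **kwargs)

    # -- lookups ----------------------------------------------------------

    def flags(self, collection_size: int | None = None):
        self._check_fitted()
        return _apply.flag_ravs(self, collection_size)

    def find_studies_in_cluster(self, rav_id: str) -> pd.DataFrame:
        self._check_fitted()
        return _apply.find_studies_in_cluster(self, rav_id)

    def subset_enriched_pathways(self, rav_id: str, n: int = 10) -> pd.DataFrame:
        self._check_fitted()
        return _apply.subset_enriched_pathways(self, rav_id, n)

    def mesh_table(self, rav_id: str) -> pd.DataFrame:
        self._check_fitted()
        return _apply.mesh_table(self, rav_id)
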