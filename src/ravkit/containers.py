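"""In-memory containers shared across the pipeline.

Expression data travels as :class:`ExpressionMatrix` (a labelled genes x
samples matrix with a value-scale tag), per-study decompositions as
:class:`PCResult`, the pooled loading collection as :class:`PooledLoadings`,
and the clustered, averaged index as :class:`RAVIndex`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "NormalizationStats",
    "PCResult",
    "PooledLoadings",
    "ClusterAssignment",
    "RAVIndex",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one study.

    Parameters
    ----------
    study_id : str
        Identifier of the study the samples belong to.
    data : pandas.DataFrame
        Genes in rows (index = gene identifiers), samples in columns
        (columns = sample identifiers). Values are 64-bit reals.
    scale : {"counts", "log"}
        Whether values are raw (non-negative) counts or log-scale
        expression. Counts must be routed through
        :func:`ravkit.preprocess.cpm_filter` before PCA.
    """

    study_id: str
    data: pd.DataFrame
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log"):
            raise ValueError(f"scale must be 'counts' or 'log', got {self.scale!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene IDs in study {self.study_id}: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicate sample IDs in study {self.study_id}: {dup}")
        self.data = self.data.astype(np.float64, copy=False)
        if self.scale == "counts" and (self.data.to_numpy() < 0).any():
            raise ValueError(f"negative values in counts matrix for study {self.study_id}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict(self, genes) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` (in the given order)."""
        missing = pd.Index(genes).difference(self.data.index)
        if len(missing):
            raise KeyError(
                f"study {self.study_id} lacks {len(missing)} requested genes "
                f"(e.g. {missing[:3].tolist()})"
            )
        return ExpressionMatrix(self.study_id, self.data.loc[list(genes)].copy(), self.scale)


@dataclass
class NormalizationStats:
    """Per-gene mean and standard deviation over a pooled sample set."""

    gene_ids: pd.Index
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if not (len(self.gene_ids) == len(self.mean) == len(self.sd)):
            raise ValueError("gene_ids, mean and sd must have equal length")
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd}, index=self.gene_ids)


@dataclass
class PCResult:
    """Loadings and variance-explained fractions of one study's PCA.

    ``loadings`` is genes x k with unit-norm columns named PC1..PCk, ordered
    by decreasing variance explained.
    """

    study_id: str
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        self.variance_explained = np.asarray(self.variance_explained, dtype=np.float64)
        if self.loadings.shape[1] != len(self.variance_explained):
            raise ValueError("one variance-explained fraction per loading required")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PooledLoadings:
    """All loading vectors pooled across studies (genes x P).

    ``provenance`` has one row per pooled column with columns
    ``study_id``, ``pc`` (1-based PC number within its study),
    ``variance_explained`` and ``is_control``.
    """

    loadings: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.loadings.shape[1] != len(self.provenance):
            raise ValueError("provenance must have one row per pooled column")
        required = {"study_id", "pc", "variance_explained", "is_control"}
        missing = required - set(self.provenance.columns)
        if missing:
            raise ValueError(f"provenance missing columns: {sorted(missing)}")
        norms = np.linalg.norm(self.loadings.to_numpy(), axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("pooled loading columns must be unit-norm")

    @property
    def n_columns(self) -> int:
        return self.loadings.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.loadings.index


@dataclass
class ClusterAssignment:
    """Cluster labels 1..K, one per pooled loading column."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or uniq.max() > self.n_clusters:
            raise ValueError("labels must lie in 1..n_clusters")
        if len(uniq) != self.n_clusters:
            raise ValueError("labels must use every cluster id 1..n_clusters")

    def members(self, k: int) -> np.ndarray:
        """Column indices assigned to cluster ``k`` (1-based label)."""
        return np.flatnonzero(self.labels == k)


@dataclass
class RAVIndex:
    """Averaged loadings (genes x K) with per-cluster bookkeeping.

    ``ravs`` columns are named RAV1..RAVK. ``cluster_info`` is indexed by
    RAV name with columns ``size``, ``avg_sw``, ``mean_var_explained``.
    ``provenance`` extends the pooled provenance with a ``rav`` column.
    """

    ravs: pd.DataFrame
    cluster_info: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if int(self.cluster_info["size"].sum()) != len(self.provenance):
            raise ValueError("cluster sizes must sum to the number of pooled columns")
        if set(self.cluster_info.index) != set(self.ravs.columns):
            raise ValueError("cluster_info index must match RAV columns")

    @property
    def n_ravs(self) -> int:
        return self.ravs.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.ravs.index

    def members_of(self, rav_id: str) -> pd.DataFrame:
        if rav_id not in self.ravs.columns:
            raise KeyError(f"unknown RAV id: {rav_id}")
        return self.provenance[self.provenance["rav"] == rav_id]
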