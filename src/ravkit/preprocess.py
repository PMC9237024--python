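"""Study-level preprocessing: filtering, gene harmonisation, normalisation, PCA.

Training studies arrive as log-scale genes x samples matrices. The pipeline
keeps each study's most variable genes, intersects gene lists across
studies, row-normalises over the pooled sample set (not per study), and
decomposes each study by PCA of its gene-centered matrix. Count matrices
destined for validation go through :func:`cpm_filter` instead.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NormalizationStats, PCResult

__all__ = [
    "study_filter",
    "top_variable_genes",
    "common_genes",
    "pooled_row_normalize",
    "dataset_pca",
    "cpm_filter",
    "read_expression_tsv",
    "read_study_metadata",
]

#: MeSH terms that exclude a study from training.
EXCLUDED_MESH_TERMS = frozenset({"Single-Cell Analysis"})


def study_filter(
    study_meta: pd.DataFrame,
    min_samples: int = 50,
    max_samples: int = 1000,
    excluded_terms: Iterable[str] = EXCLUDED_MESH_TERMS,
) -> pd.Series:
    """Decide which studies enter training.

    A study is kept when ``min_samples <= sampleCount <= max_samples`` and
    none of its MeSH terms is in ``excluded_terms`` (single-cell studies are
    excluded because their variance structure differs from bulk profiles).
    Records with a missing sample count are rejected with a warning.

    Parameters
    ----------
    study_meta : DataFrame
        One row per study with columns ``sampleCount`` and (optionally)
        ``meshTerms`` holding a list or a pipe-separated string of terms.

    Returns
    -------
    Series of bool indexed like ``study_meta``.
    """
    if "sampleCount" not in study_meta.columns:
        raise ValueError("study metadata must have a 'sampleCount' column")
    excluded_terms = set(excluded_terms)
    include = pd.Series(True, index=study_meta.index)

    counts = pd.to_numeric(study_meta["sampleCount"], errors="coerce")
    missing = counts.isna()
    if missing.any():
        warnings.warn(
            f"rejecting {int(missing.sum())} studies with missing sampleCount: "
            f"{study_meta.index[missing][:5].tolist()}"
        )
        include[missing] = False
    include &= (counts >= min_samples) & (counts <= max_samples)

    if "meshTerms" in study_meta.columns:
        for idx, terms in study_meta["meshTerms"].items():
            if terms is None or (isinstance(terms, float) and math.isnan(terms)):
                continue
            if isinstance(terms, str):
                terms = [t.strip() for t in terms.split("|") if t.strip()]
            if excluded_terms.intersection(terms):
                include[idx] = False
    return include


def top_variable_genes(m: ExpressionMatrix, q: float = 0.90) -> pd.Index:
    """Genes in the top ``q`` fraction by within-study standard deviation.

    Keeps the ``ceil(q * n_genes)`` highest-sd genes; ties at the threshold
    sd are all retained, so the result can be larger under ties.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if m.n_samples < 2:
        raise ValueError(f"study {m.study_id}: need >= 2 samples to compute gene sds")
    sds = m.data.std(axis=1, ddof=1)
    k = math.ceil(q * len(sds))
    threshold = np.sort(sds.to_numpy())[::-1][k - 1]
    return m.gene_ids[(sds >= threshold).to_numpy()]


def common_genes(gene_lists: Sequence[Iterable[str]]) -> list[str]:
    """Exact intersection of gene lists, returned in lexicographic order."""
    if len(gene_lists) == 0:
        raise ValueError("need at least one gene list")
    common = set(gene_lists[0])
    for gl in gene_lists[1:]:
        common &= set(gl)
    if not common:
        warnings.warn("gene lists have an empty intersection")
    return sorted(common)


def pooled_row_normalize(
    studies: Sequence[ExpressionMatrix],
    genes: Sequence[str],
) -> tuple[list[ExpressionMatrix], NormalizationStats, list[str]]:
    """Z-score each gene over the pooled samples of all studies.

    The per-gene mean and sd are computed over the concatenation of every
    sample from every study — not per study — so scale differences between
    studies are preserved in the normalised values. Genes with zero pooled
    sd carry no information and are dropped with a warning.

    Returns
    -------
    (normalized studies, stats, dropped_genes)
        ``stats`` holds the pooled mean/sd for the retained genes so the
        same transformation can be reapplied (e.g. to negative controls).
    """
    genes = list(genes)
    restricted = [s.restrict(genes) for s in studies]
    pooled = np.hstack([s.data.to_numpy() for s in restricted])
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=1)

    zero = sd == 0
    dropped = [g for g, z in zip(genes, zero) if z]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} genes with zero pooled sd")
        keep = ~zero
        genes = [g for g, k in zip(genes, keep) if k]
        mean, sd = mean[keep], sd[keep]
        restricted = [s.restrict(genes) for s in restricted]

    stats = NormalizationStats(pd.Index(genes), mean, sd)
    normalized = [
        ExpressionMatrix(
            s.study_id,
            s.data.sub(mean, axis=0).div(sd, axis=0),
            "log",
        )
        for s in restricted
    ]
    return normalized, stats, dropped


def apply_row_normalization(m: ExpressionMatrix, stats: NormalizationStats) -> ExpressionMatrix:
    """Apply previously computed pooled mean/sd to a matrix (gene-matched)."""
    r = m.restrict(stats.gene_ids)
    data = r.data.sub(stats.mean, axis=0).div(stats.sd, axis=0)
    return ExpressionMatrix(m.study_id, data, "log")


def dataset_pca(m: ExpressionMatrix, k: int = 20) -> PCResult:
    """PCA of one study: gene rows centered (not scaled), SVD, top-k loadings.

    Loadings are the left singular vectors (gene space, unit norm), ordered
    by decreasing variance explained; each PC's variance-explained fraction
    is its squared singular value over the total. Sign is fixed so the
    largest-magnitude entry of each loading is positive, removing the
    decomposition's sign ambiguity before pooling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.n_samples < 2:
        raise ValueError(f"study {m.study_id}: PCA needs >= 2 samples")
    if m.scale != "log":
        raise ValueError(f"study {m.study_id}: PCA input must be log-scale")
    X = m.data.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    tol = s[0] * max(Xc.shape) * np.finfo(np.float64).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank < k:
        warnings.warn(f"study {m.study_id}: rank {rank} < requested k={k}; truncating")
    ncomp = min(k, rank)
    U = U[:, :ncomp]
    # deterministic sign: largest-|entry| positive; ties resolved by argmax
    flip = U[np.abs(U).argmax(axis=0), np.arange(ncomp)] < 0
    U = U * np.where(flip, -1.0, 1.0)
    varexp = (s[:ncomp] ** 2) / total
    loadings = pd.DataFrame(
        U, index=m.gene_ids, columns=[f"PC{i + 1}" for i in range(ncomp)]
    )
    return PCResult(m.study_id, loadings, varexp)


def cpm_filter(
    counts: ExpressionMatrix,
    threshold: float = 2.0,
    mode: str = "any",
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """CPM-filter a count matrix and return log2, gene-centered expression.

    CPM = count / library size x 1e6. With ``mode="any"`` (default) a gene
    survives when its CPM reaches ``threshold`` in at least one sample;
    ``mode="all"`` requires every sample. Survivors are transformed to
    log2(count + pseudocount) and centered per gene.
    """
    if counts.scale != "counts":
        raise ValueError("cpm_filter expects a counts-scale matrix")
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    lib = counts.data.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {zero.index[:5].tolist()}")
    cpm = counts.data.div(lib, axis=1) * 1e6
    passing = cpm.max(axis=1) >= threshold if mode == "any" else cpm.min(axis=1) >= threshold
    kept = counts.data.loc[passing.to_numpy()]
    logged = np.log2(kept + pseudocount)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    return ExpressionMatrix(counts.study_id, centered, "log")


# ---------------------------------------------------------------------------
# file interfaces

def read_expression_tsv(path, study_id: str, scale: str = "log", sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples table (first column gene IDs, header sample IDs)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(study_id, df, scale)


def write_expression_tsv(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    m.data.to_csv(path, sep=sep, index_label="gene")


def read_expression_mtx(
    mtx_path, gene_path, sample_path, study_id: str, scale: str = "counts"
) -> ExpressionMatrix:
    """Read a MatrixMarket matrix (genes x samples) with row/column name files.

    ``gene_path`` and ``sample_path`` are plain text, one identifier per
    line, in matrix order.
    """
    from scipy.io import mmread

    m = mmread(mtx_path)
    values = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=np.float64)
    genes = [line.strip() for line in open(gene_path) if line.strip()]
    samples = [line.strip() for line in open(sample_path) if line.strip()]
    if values.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {values.shape} does not match {len(genes)} genes "
            f"x {len(samples)} samples"
        )
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(study_id, df, scale)


def read_study_metadata(path) -> pd.DataFrame:
    """Read the study metadata TSV (studyId, sampleCount, title, meshTerms).

    ``meshTerms`` is pipe-separated in the file and parsed into lists.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"studyId": str})
    if "studyId" not in meta.columns:
        raise ValueError("metadata must have a 'studyId' column")
    meta = meta.set_index("studyId")
    if "meshTerms" in meta.columns:
        meta["meshTerms"] = meta["meshTerms"].apply(
            lambda v: [] if pd.isna(v) else [t.strip() for t in str(v).split("|") if t.strip()]
        )
    return meta
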