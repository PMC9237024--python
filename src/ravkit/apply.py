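"""Interpret a new dataset against a fitted RAV model.

Validation asks which RAVs are reproduced by the new dataset: the dataset
is decomposed by PCA and each of its top loading vectors is correlated
(Pearson, over the common genes) with every RAV; a RAV's validation score
is the maximum over the dataset's PCs. Sample scores project each sample's
standardized expression profile onto a RAV, giving a per-sample activity
value for that latent axis, which can then be associated with sample
metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from . import preprocess

__all__ = [
    "ValidationResult",
    "validate",
    "heatmap_table",
    "sample_scores",
    "meta_association_r2",
    "flag_ravs",
    "flag_message",
    "find_studies_in_cluster",
    "subset_enriched_pathways",
    "mesh_table",
]


@dataclass
class ValidationResult:
    """Correlations between a new dataset's PCs and every RAV.

    ``correlations`` is PCs x RAVs; ``scores`` is the per-RAV validation
    score (column maximum, signed); ``avg_sw`` carries each RAV's average
    silhouette width from the model; ``contributing_pc`` names the PC
    attaining the score.
    """

    dataset_id: str
    correlations: pd.DataFrame
    scores: pd.Series
    avg_sw: pd.Series
    contributing_pc: pd.Series

    def top(self, n: int = 5) -> pd.DataFrame:
        """Top-n validated RAVs with their scores and silhouette widths."""
        top = self.scores.sort_values(ascending=False).head(n)
        return pd.DataFrame(
            {
                "score": top,
                "avg_sw": self.avg_sw[top.index],
                "contributing_pc": self.contributing_pc[top.index],
            }
        )


def _prepare_common(new: ExpressionMatrix, model, min_genes: int):
    """Route counts through the CPM filter, intersect with model genes."""
    if new.scale == "counts":
        new = preprocess.cpm_filter(new)
    model_genes = model.rav_index_.gene_ids
    common = model_genes.intersection(new.gene_ids)
    if len(common) < min_genes:
        raise ValueError(
            f"only {len(common)} genes shared with the model "
            f"(floor {min_genes}); cannot proceed"
        )
    if len(common) < 0.5 * len(model_genes):
        warnings.warn(
            f"gene overlap {len(common)} is below half of the model's "
            f"{len(model_genes)} genes; interpret with caution"
        )
    return new, common


def validate(
    new: ExpressionMatrix,
    model,
    n_pc: int = 8,
    min_genes: int = 1000,
) -> ValidationResult:
    """Validation scores of every RAV against a new dataset.

    The new matrix (counts are CPM-filtered and log-transformed first) is
    restricted to the genes shared with the model, gene-centered, and
    decomposed by PCA. Each of the top ``n_pc`` loading vectors is
    Pearson-correlated with every RAV over the common genes; the per-RAV
    score is the signed maximum over PCs (RAV orientation is a convention,
    so strongly negative correlations can be inspected in
    ``correlations``).
    """
    new, common = _prepare_common(new, model, min_genes)
    restricted = new.restrict(common)
    pca = preprocess.dataset_pca(restricted, k=n_pc)
    if pca.n_components < n_pc:
        warnings.warn(
            f"only {pca.n_components} PCs available (requested {n_pc})"
        )
    L = pca.loadings.to_numpy()  # genes x n_pc
    R = model.rav_index_.ravs.loc[common].to_numpy()  # genes x K

    Lc = L - L.mean(axis=0, keepdims=True)
    Rc = R - R.mean(axis=0, keepdims=True)
    Ln = np.linalg.norm(Lc, axis=0)
    Rn = np.linalg.norm(Rc, axis=0)
    corr = (Lc.T @ Rc) / np.outer(Ln, Rn)

    rav_names = model.rav_index_.ravs.columns
    corr_df = pd.DataFrame(corr, index=pca.loadings.columns, columns=rav_names)
    scores = corr_df.max(axis=0)
    contributing = corr_df.idxmax(axis=0)
    avg_sw = model.rav_index_.cluster_info["avg_sw"].reindex(rav_names)
    return ValidationResult(new.study_id, corr_df, scores, avg_sw, contributing)


def heatmap_table(
    results: Sequence[ValidationResult],
    cutoff: float | None = 0.7,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Tabulate validation scores across datasets, RAVs x datasets.

    A RAV row is kept when any dataset's score exceeds ``cutoff`` (the
    display convention for validation heatmaps), or — when ``top_n`` is
    given instead — when it is among some dataset's ``top_n`` scores.
    """
    if not results:
        raise ValueError("need at least one ValidationResult")
    table = pd.DataFrame({r.dataset_id: r.scores for r in results})
    if top_n is not None:
        keep: set[str] = set()
        for col in table.columns:
            keep |= set(table[col].nlargest(top_n).index)
        rows = [r for r in table.index if r in keep]
    else:
        rows = table.index[(table > cutoff).any(axis=1)]
    return table.loc[rows]


def sample_scores(
    new: ExpressionMatrix,
    model,
    rav_ids: Sequence[str] | None = None,
    min_genes: int = 1000,
) -> pd.DataFrame:
    """Project samples onto RAV loadings: a samples x RAVs score matrix.

    Gene rows of the new dataset (restricted to the common genes, after
    dropping zero-variance rows) are z-scored over the dataset's own
    samples; the score of sample j on a RAV is the inner product of j's
    z-vector with the RAV loading restricted to the common genes, divided
    by (number of common genes x restricted loading norm). The divisor is
    a scale stabiliser only: any strictly monotone rescaling preserves all
    rank- and correlation-based downstream results.
    """
    index = model.rav_index_
    if rav_ids is None:
        rav_ids = list(index.ravs.columns)
    unknown = [r for r in rav_ids if r not in index.ravs.columns]
    if unknown:
        raise KeyError(f"unknown RAV id(s): {unknown}")
    new, common = _prepare_common(new, model, min_genes)
    data = new.restrict(common).data
    sd = data.std(axis=1, ddof=1)
    nonzero = sd > 0
    if not nonzero.all():
        data = data.loc[nonzero]
    Z = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0)
    R = index.ravs.loc[data.index, list(rav_ids)].to_numpy()
    norms = np.linalg.norm(R, axis=0)
    if (norms == 0).any():
        raise ValueError("RAV loading has zero norm on the common genes")
    scores = (Z.to_numpy().T @ R) / (len(data.index) * norms)
    return pd.DataFrame(scores, index=new.sample_ids, columns=list(rav_ids))


def meta_association_r2(
    scores: pd.DataFrame, variable: pd.Series | np.ndarray
) -> tuple[pd.Series, str]:
    """R-squared between a continuous sample variable and each RAV's scores.

    Missing values are dropped pairwise; at least three complete pairs are
    required per RAV. Returns the per-RAV R^2 vector (squared Pearson
    correlation) and the best-associated RAV id.
    """
    variable = pd.Series(np.asarray(variable, dtype=np.float64), index=scores.index)
    r2 = {}
    for rav in scores.columns:
        pair = pd.concat([scores[rav], variable], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(f"{rav}: fewer than 3 complete pairs")
        v = pair.iloc[:, 1]
        if v.nunique() == 1:
            raise ValueError("variable is constant over the complete pairs")
        if pair.iloc[:, 0].nunique() == 1:
            r2[rav] = 0.0
            continue
        r = np.corrcoef(pair.iloc[:, 0], v)[0, 1]
        r2[rav] = float(r * r)
    out = pd.Series(r2, name="r_squared")
    return out, str(out.idxmax())


# ---------------------------------------------------------------------------
# interpretation flags and lookup helpers

FLAG_SINGLE_ELEMENT = "SINGLE_ELEMENT"
FLAG_ANNOTATION_OUT_OF_RANGE = "ANNOTATION_OUT_OF_RANGE"
FLAG_SINGLE_STUDY = "SINGLE_STUDY"


def flag_ravs(model, collection_size: int | None = None) -> dict[str, set[str]]:
    """Interpretation caveats per RAV.

    ``SINGLE_ELEMENT``: cluster of one PC (not a replicated signal);
    ``ANNOTATION_OUT_OF_RANGE``: zero enriched sets, or more than 5% of the
    input collection ("too many" — e.g. threshold 276 for a 5520-set
    collection); ``SINGLE_STUDY``: a multi-PC cluster whose members all
    come from one study (within-study redundancy, not replication).
    """
    index = model.rav_index_
    info = index.cluster_info
    gsea = getattr(model, "gsea_", None)
    if collection_size is None:
        collection_size = getattr(model, "gsea_collection_size_", None)
    flags: dict[str, set[str]] = {rav: set() for rav in index.ravs.columns}
    counts = gsea.groupby("rav").size() if gsea is not None and not gsea.empty else pd.Series(dtype=int)
    too_many = round(0.05 * collection_size) if collection_size else None
    for rav in index.ravs.columns:
        size = int(info.loc[rav, "size"])
        if size == 1:
            flags[rav].add(FLAG_SINGLE_ELEMENT)
        members = index.provenance[index.provenance["rav"] == rav]
        if size > 1 and members["study_id"].nunique() == 1:
            flags[rav].add(FLAG_SINGLE_STUDY)
        if gsea is not None and too_many is not None:
            n_sets = int(counts.get(rav, 0))
            if n_sets == 0 or n_sets > too_many:
                flags[rav].add(FLAG_ANNOTATION_OUT_OF_RANGE)
    return flags


def flag_message(flags: Mapping[str, set[str]], rav_ids: Sequence[str]) -> str | None:
    """User-facing caveat message when any requested RAV carries flags."""
    flagged = {r: sorted(flags[r]) for r in rav_ids if flags.get(r)}
    if not flagged:
        return None
    parts = [f"{r}: {', '.join(f)}" for r, f in flagged.items()]
    return (
        "Interpret with caution - the following RAVs carry caveats ("
        + "; ".join(parts)
        + ")"
    )


def find_studies_in_cluster(model, rav_id: str) -> pd.DataFrame:
    """Studies contributing to a RAV, with PC numbers and variance explained."""
    members = model.rav_index_.members_of(rav_id)
    members = members[~members["is_control"]].copy()
    meta = getattr(model, "study_meta_", None)
    if meta is not None and "title" in getattr(meta, "columns", []):
        members["title"] = [
            meta["title"].get(sid, "") for sid in members["study_id"]
        ]
    return members.reset_index(drop=True)


def subset_enriched_pathways(model, rav_id: str, n: int = 10) -> pd.DataFrame:
    """Top-n stored enrichments of one RAV, ordered by |NES|."""
    if rav_id not in model.rav_index_.ravs.columns:
        raise KeyError(f"unknown RAV id: {rav_id}")
    gsea = getattr(model, "gsea_", None)
    if gsea is None:
        raise ValueError("model has no stored enrichment; run annotate_gsea first")
    rows = gsea[gsea["rav"] == rav_id]
    return rows.reindex(rows["nes"].abs().sort_values(ascending=False).index).head(n)


def mesh_table(model, rav_id: str) -> pd.DataFrame:
    """Scored MeSH terms of one RAV, descending."""
    if rav_id not in model.rav_index_.ravs.columns:
        raise KeyError(f"unknown RAV id: {rav_id}")
    mesh = getattr(model, "mesh_", None)
    if mesh is None:
        raise ValueError("model has no MeSH annotation; run annotate_mesh first")
    return (
        mesh[mesh["rav"] == rav_id]
        .sort_values("score", ascending=False)
        .reset_index(drop=True)
    )
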