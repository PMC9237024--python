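"""Annotate RAVs with gene-set enrichment and MeSH term scores.

Each RAV loading is interpreted two ways. First by pre-ranked gene-set
enrichment: genes are ordered by loading value and a weighted
Kolmogorov-Smirnov running-sum statistic (weight exponent 1) is computed
per gene set, with a gene-label permutation null, sign-matched NES
normalisation and BH-adjusted p-values. Second by a bag-of-words score
over the MeSH terms of the studies contributing to the RAV: each term is
weighted by the variance explained by the member PCs that carry it and
down-weighted by the term's frequency in the training universe, after
cluster-size-dependent noise filters and a user drop-list.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "filter_sets",
    "enrichment_score",
    "preranked_gsea",
    "bh_adjust",
    "select_enriched",
    "annotate_gsea",
    "pathway_coverage",
    "pathway_separation",
    "mesh_universe",
    "mesh_score",
    "annotate_mesh",
    "DEFAULT_DROP_LIST",
]

#: Uninformative terms excluded from MeSH scoring by default.
DEFAULT_DROP_LIST = ("Humans", "RNA Sequencing")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and a source label."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, member genes)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need >= 3 fields)")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"{path}: set {name!r} at line {lineno} has no members")
            sets[name] = members
            desc[name] = fields[1]
    return GeneSetCollection(sets, desc, source=str(path))


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write("\t".join([name, coll.descriptions.get(name, "")] + list(members)) + "\n")


def filter_sets(coll: GeneSetCollection, min_size: int = 10, max_size: int = 500) -> GeneSetCollection:
    """Drop sets with fewer than ``min_size`` or more than ``max_size``
    members (both bounds inclusive for kept sets)."""
    kept = {n: m for n, m in coll.sets.items() if min_size <= len(m) <= max_size}
    return GeneSetCollection(
        kept, {n: coll.descriptions.get(n, "") for n in kept}, coll.source
    )


# ---------------------------------------------------------------------------
# pre-ranked GSEA


def enrichment_score(ranked_values: np.ndarray, in_set: np.ndarray, p: float = 1.0) -> float:
    """Weighted KS enrichment score of a set over a ranked list.

    ``ranked_values`` are the ranking metric values sorted in decreasing
    order; ``in_set`` is the boolean membership mask in the same order.
    Hits advance the running sum by |value|^p normalised over in-set
    values; misses retreat by 1/(N - Nh). The ES is the running-sum value
    of largest magnitude (signed).
    """
    r = np.abs(np.asarray(ranked_values, dtype=np.float64)) ** p
    in_set = np.asarray(in_set, dtype=bool)
    nh = int(in_set.sum())
    N = len(r)
    if nh < 1 or nh >= N:
        raise ValueError("set must contain between 1 and N-1 ranked genes")
    hit_norm = r[in_set].sum()
    if hit_norm == 0:
        # all in-set metric values zero: fall back to unweighted steps
        steps = np.where(in_set, 1.0 / nh, -1.0 / (N - nh))
    else:
        steps = np.where(in_set, r / hit_norm, -1.0 / (N - nh))
    running = np.cumsum(steps)
    return float(running[np.abs(running).argmax()])


def _null_es_permutation(
    ranked_values: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    N = len(ranked_values)
    null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(N, dtype=bool)
        mask[rng.choice(N, size=n_hits, replace=False)] = True
        null[i] = enrichment_score(ranked_values, mask)
    return null


def _null_es_exhaustive(ranked_values: np.ndarray, n_hits: int) -> np.ndarray:
    N = len(ranked_values)
    null = []
    for combo in itertools.combinations(range(N), n_hits):
        mask = np.zeros(N, dtype=bool)
        mask[list(combo)] = True
        null.append(enrichment_score(ranked_values, mask))
    return np.asarray(null)


def preranked_gsea(
    loading: pd.Series,
    coll: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Pre-ranked GSEA of one loading vector against a gene-set collection.

    Genes are ranked by decreasing loading value. The null distribution
    comes from gene-label permutations (random same-size subsets); with
    ``method="exhaustive"`` every subset is enumerated (feasible only for
    small lists) and the permutation p-value is exact. The p-value is
    two-sided on |ES|; NES divides ES by the mean |null ES| of matching
    sign. Sets with fewer than two genes present in the ranking are
    skipped with a note.

    Returns a DataFrame with one row per evaluated set: ``set``, ``size``
    (genes present), ``es``, ``nes``, ``pvalue``, ``description``.
    """
    if method not in ("permutation", "exhaustive"):
        raise ValueError("method must be 'permutation' or 'exhaustive'")
    loading = loading.dropna()
    order = np.argsort(-loading.to_numpy(), kind="stable")
    ranked_genes = loading.index.to_numpy()[order]
    ranked_values = loading.to_numpy()[order]
    gene_pos = {g: i for i, g in enumerate(ranked_genes)}
    N = len(ranked_genes)

    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in coll.sets.items():
        pos = [gene_pos[g] for g in set(members) if g in gene_pos]
        if len(pos) < 2:
            warnings.warn(f"set {name!r}: fewer than 2 genes present; skipped")
            continue
        if len(pos) >= N:
            warnings.warn(f"set {name!r} covers the whole ranking; skipped")
            continue
        mask = np.zeros(N, dtype=bool)
        mask[pos] = True
        es = enrichment_score(ranked_values, mask)
        nh = len(pos)
        if nh not in null_cache:
            if method == "exhaustive":
                if math.comb(N, nh) > 200_000:
                    raise ValueError(
                        f"exhaustive enumeration infeasible: C({N},{nh}) subsets"
                    )
                null_cache[nh] = _null_es_exhaustive(ranked_values, nh)
            else:
                null_cache[nh] = _null_es_permutation(ranked_values, nh, n_perm, rng)
        null = null_cache[nh]
        if method == "exhaustive":
            pvalue = float((np.abs(null) >= abs(es) - 1e-12).mean())
        else:
            pvalue = float((1 + (np.abs(null) >= abs(es) - 1e-12).sum()) / (1 + len(null)))
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and not np.isnan(denom) else np.nan
        rows.append((name, nh, es, nes, pvalue, coll.descriptions.get(name, "")))
    return pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "pvalue", "description"]
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_enriched(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep rows significant at BH-adjusted p < alpha, then retain those
    attaining the minimum q-value (ties kept)."""
    if rows.empty:
        return rows
    sig = rows[rows["qvalue"] < alpha]
    if sig.empty:
        return sig
    return sig[sig["qvalue"] == sig["qvalue"].min()]


def annotate_gsea(
    model,
    coll: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    keep: str = "min_q",
) -> pd.DataFrame:
    """Run pre-ranked GSEA on every RAV of a fitted model and store results.

    ``keep="min_q"`` stores, per RAV, the significant rows attaining the
    minimum q-value (the model's headline annotation); ``keep="significant"``
    stores all rows with q < alpha. The stored table (columns ``rav``,
    ``set``, ``es``, ``nes``, ``pvalue``, ``qvalue``, ``description``) is
    attached to the model as ``gsea_`` together with the collection size
    (``gsea_collection_size_``).
    """
    if keep not in ("min_q", "significant"):
        raise ValueError("keep must be 'min_q' or 'significant'")
    index = model.rav_index_
    out = []
    sub_seeds = np.random.SeedSequence(seed).spawn(index.n_ravs)
    for i, rav in enumerate(index.ravs.columns):
        rows = preranked_gsea(
            index.ravs[rav], coll, n_perm=n_perm,
            seed=int(sub_seeds[i].generate_state(1)[0] % (2**31)),
        )
        if rows.empty:
            continue
        rows = rows.copy()
        rows["qvalue"] = bh_adjust(rows["pvalue"].to_numpy())
        kept = select_enriched(rows, alpha) if keep == "min_q" else rows[rows["qvalue"] < alpha]
        if kept.empty:
            continue
        kept = kept.copy()
        kept.insert(0, "rav", rav)
        out.append(kept)
    table = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["rav", "set", "size", "es", "nes", "pvalue", "qvalue", "description"])
    )
    model.gsea_ = table
    model.gsea_collection_size_ = len(coll)
    return table


def pathway_coverage(model, coll: GeneSetCollection) -> float:
    """Fraction of supplied gene sets annotating at least one RAV."""
    if len(coll) == 0:
        raise ValueError("empty gene-set collection")
    table = getattr(model, "gsea_", None)
    if table is None:
        raise ValueError("model has no stored enrichment; run annotate_gsea first")
    return len(set(table["set"]) & set(coll.sets)) / len(coll)


def pathway_separation(
    model,
    pair_groups: Sequence[tuple[str, str, str]],
    top_n: int = 1,
) -> pd.DataFrame:
    """Can the model's top enrichments tell related pathway families apart?

    ``pair_groups`` is a sequence of (label, pattern_a, pattern_b); patterns
    are case-insensitive substrings of pathway names. A pair is separated
    when some RAV's top-``top_n`` enrichments (by |NES|) match side A only,
    some other RAV's match side B only, and no RAV's top-``top_n`` match
    both sides.
    """
    table = getattr(model, "gsea_", None)
    if table is None or table.empty:
        raise ValueError("model has no stored enrichment")
    top = (
        table.assign(_mag=table["nes"].abs())
        .sort_values(["rav", "_mag"], ascending=[True, False])
        .groupby("rav", sort=False)
        .head(top_n)
    )
    rows = []
    for label, pat_a, pat_b in pair_groups:
        a_only = b_only = both = 0
        matched_any = False
        for _, sub in top.groupby("rav", sort=False):
            names = sub["set"].str.lower()
            has_a = names.str.contains(pat_a.lower(), regex=False).any()
            has_b = names.str.contains(pat_b.lower(), regex=False).any()
            matched_any |= has_a or has_b
            if has_a and has_b:
                both += 1
            elif has_a:
                a_only += 1
            elif has_b:
                b_only += 1
        if not matched_any:
            warnings.warn(f"pair {label!r}: patterns match no stored enrichment")
        rows.append((label, a_only, b_only, both, a_only > 0 and b_only > 0 and both == 0))
    return pd.DataFrame(
        rows, columns=["pair", "n_rav_a_only", "n_rav_b_only", "n_rav_both", "separated"]
    ).set_index("pair")


# ---------------------------------------------------------------------------
# MeSH scoring


def mesh_universe(provenance: pd.DataFrame, study_terms: Mapping[str, Sequence[str]]) -> pd.Series:
    """Bag-of-words term frequencies over all training PCs' studies.

    Each pooled PC contributes its study's full term list, so a term's
    universe frequency counts occurrences with multiplicity.
    """
    counts: dict[str, int] = {}
    for sid in provenance.loc[~provenance["is_control"], "study_id"]:
        for term in study_terms.get(sid, ()):  # controls carry no metadata
            counts[term] = counts.get(term, 0) + 1
    return pd.Series(counts, dtype=float).sort_values(ascending=False)


def mesh_score(
    members: pd.DataFrame,
    study_terms: Mapping[str, Sequence[str]],
    universe: pd.Series,
    drop_list: Iterable[str] = DEFAULT_DROP_LIST,
    small_cluster_limit: int = 8,
    small_fraction: float = 0.5,
    large_min_count: int = 4,
) -> pd.Series:
    """Score MeSH terms for one RAV.

    ``members`` is the RAV's provenance slice (columns ``study_id``,
    ``variance_explained``). Scoring: (1) drop ``drop_list`` terms; (2)
    noise filter — clusters with fewer than ``small_cluster_limit`` PCs
    drop terms occurring on at most ``small_fraction x cluster size``
    member PCs, larger clusters drop terms occurring at most
    ``large_min_count`` times; (3) score(term) = sum of the variance
    explained by the member PCs whose study carries the term, divided by
    the term's universe frequency. Returned in descending score order.
    """
    drop = set(drop_list)
    size = len(members)
    term_varexp: dict[str, float] = {}
    term_count: dict[str, int] = {}
    for _, row in members.iterrows():
        sid = row["study_id"]
        if sid not in study_terms:
            raise KeyError(f"no MeSH metadata for study {sid!r}")
        for term in set(study_terms[sid]):
            if term in drop:
                continue
            term_varexp[term] = term_varexp.get(term, 0.0) + float(row["variance_explained"])
            term_count[term] = term_count.get(term, 0) + 1

    threshold = small_fraction * size if size < small_cluster_limit else large_min_count
    scores = {}
    for term, ve in term_varexp.items():
        if term_count[term] <= threshold:
            continue
        freq = universe.get(term, np.nan)
        if not freq or np.isnan(freq):
            raise KeyError(f"term {term!r} absent from the universe frequencies")
        scores[term] = ve / freq
    return pd.Series(scores, dtype=float).sort_values(ascending=False).rename("score")


def annotate_mesh(
    model,
    study_terms: Mapping[str, Sequence[str]],
    drop_list: Iterable[str] = DEFAULT_DROP_LIST,
    **kwargs,
) -> pd.DataFrame:
    """Score MeSH terms for every RAV of a fitted model and store the table.

    Attaches ``mesh_`` (columns ``rav``, ``term``, ``score``) and
    ``mesh_universe_`` to the model.
    """
    index = model.rav_index_
    prov = index.provenance
    universe = mesh_universe(prov, study_terms)
    out = []
    for rav in index.ravs.columns:
        members = prov[(prov["rav"] == rav) & (~prov["is_control"])]
        if members.empty:
            continue
        scores = mesh_score(members, study_terms, universe, drop_list, **kwargs)
        for term, score in scores.items():
            out.append((rav, term, score))
    table = pd.DataFrame(out, columns=["rav", "term", "score"])
    model.mesh_ = table
    model.mesh_universe_ = universe
    return table
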