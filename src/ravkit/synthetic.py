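"""Synthetic corpora: planted-factor training sets, negative and positive controls.

The clustering model assumes that a biological axis of variation recurs as
a similar PCA loading across independent studies. The generators here build
multi-study corpora with exactly that structure (sparse gene programs
shared by several studies, plus noise), negative controls (gene-scrambled
real samples with a small uniform perturbation) used to calibrate the
cluster count, and bootstrap positive controls.

All generators are pure functions of their inputs and a seed; a master
seed spawns independent per-dataset sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NormalizationStats

__all__ = [
    "PlantedCorpusSpec",
    "make_planted_corpus",
    "make_negative_controls",
    "make_positive_controls",
]


def _default_sharing_map(n_studies: int, n_factors: int, studies_per_factor: int):
    """Block assignment: factor f is carried by ``studies_per_factor``
    consecutive studies starting at ``f * floor(n_studies / n_factors)``
    (wrapping mod n_studies). With ``studies_per_factor <= floor(n_studies
    / n_factors)`` — the default configuration — carrier sets are disjoint,
    so each study carries exactly one factor: the corpus then probes
    replication of an axis across independent studies without confounding
    it with within-study factor demixing."""
    sharing = {}
    stride = max(1, n_studies // max(1, n_factors))
    for f in range(n_factors):
        start = (f * stride) % n_studies
        sharing[f] = sorted({(start + j) % n_studies for j in range(studies_per_factor)})
    return sharing


@dataclass
class PlantedCorpusSpec:
    """Parameters of a planted-factor multi-study corpus.

    Defaults describe a small but realistic training condition: 20 studies
    of 50 samples over 1000 genes, five sparse gene programs (20% of genes
    each) that each recur in 4 distinct studies (disjoint carrier sets),
    with a per-loaded-gene signal standard deviation three times the noise
    standard deviation.

    ``signal_sd`` is the standard deviation that a factor of average
    strength contributes to one of its loaded genes (so
    signal_sd / noise_sd is the mean per-gene signal-to-noise amplitude
    ratio). Noise is heteroskedastic across genes: gene g's noise sd is
    ``noise_sd`` times a lognormal(0, gene_noise_sigma) scale drawn once
    per corpus and shared by every study. Gene-level variability being a
    consistent gene property is what makes per-study top-variable-gene
    lists agree across real studies; without it the intersection of
    top-90% lists collapses combinatorially. Individual factors receive
    distinct strength multipliers
    spread linearly over ``1 +/- strength_spread/2``: expression programs
    of exactly equal variance would make within-study PCA eigenvalues
    degenerate, and the returned components arbitrary rotations of the
    planted loadings — a measure-zero pathology real data does not have.
    """

    n_studies: int = 20
    n_genes: int = 1000
    n_samples: int = 50
    n_factors: int = 5
    studies_per_factor: int = 4
    sharing_map: dict[int, list[int]] | None = None
    sparsity: float = 0.20
    signal_sd: float = 3.0
    noise_sd: float = 1.0
    strength_spread: float = 0.5
    gene_noise_sigma: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def resolved_sharing(self) -> dict[int, list[int]]:
        sharing = self.sharing_map or _default_sharing_map(
            self.n_studies, self.n_factors, self.studies_per_factor
        )
        if set(sharing) != set(range(self.n_factors)):
            raise ValueError("sharing map must cover factors 0..n_factors-1")
        for f, studies in sharing.items():
            if len(studies) < 2:
                raise ValueError(f"factor {f} must be shared by >= 2 studies")
            if any(not 0 <= s < self.n_studies for s in studies):
                raise ValueError(f"factor {f} references unknown studies")
        return sharing

    def validate(self) -> None:
        for name in ("n_studies", "n_genes", "n_samples", "n_factors", "studies_per_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if self.signal_sd < 0 or self.noise_sd < 0:
            raise ValueError("signal_sd and noise_sd must be non-negative")
        if not 0 <= self.strength_spread < 2:
            raise ValueError("strength_spread must be in [0, 2)")
        if self.gene_noise_sigma < 0:
            raise ValueError("gene_noise_sigma must be non-negative")
        self.resolved_sharing()

    def factor_strengths(self) -> np.ndarray:
        """Per-factor signal sd: ``signal_sd`` scaled by multipliers spread
        linearly over 1 +/- strength_spread/2 (strongest factor first)."""
        if self.n_factors == 1:
            return np.array([self.signal_sd])
        mult = np.linspace(
            1 + self.strength_spread / 2, 1 - self.strength_spread / 2, self.n_factors
        )
        return self.signal_sd * mult


def make_planted_corpus(
    spec: PlantedCorpusSpec,
) -> tuple[list[ExpressionMatrix], pd.DataFrame, dict[int, list[int]]]:
    """Generate studies as sums of shared sparse factors plus Gaussian noise.

    Study s is ``baseline + sum_f w_f z_{s,f}^T + E`` where ``w_f`` is a
    sparse unit-norm gene loading shared across the studies carrying factor
    f, ``z_{s,f}`` are i.i.d. normal per-sample scores scaled so each loaded
    gene receives the factor's per-gene signal sd (see
    :meth:`PlantedCorpusSpec.factor_strengths`), and E is independent
    normal noise with per-gene sd ``noise_sd x gene_scale`` (gene scales
    lognormal, shared across studies). Values carry log-scale semantics.

    Returns
    -------
    (studies, truth, sharing)
        ``truth`` is the genes x factors matrix of true loadings (columns
        ``factor0``...), ``sharing`` maps factor -> carrying study indices.
    """
    spec.validate()
    sharing = spec.resolved_sharing()
    ss = np.random.SeedSequence(spec.seed)
    factor_rng = np.random.default_rng(ss.spawn(1)[0])

    genes = pd.Index([f"g{i:04d}" for i in range(spec.n_genes)], name="gene")
    gene_scale = np.exp(factor_rng.normal(0.0, spec.gene_noise_sigma, size=spec.n_genes))
    nnz = max(2, round(spec.sparsity * spec.n_genes))
    W = np.zeros((spec.n_genes, spec.n_factors))
    for f in range(spec.n_factors):
        support = factor_rng.choice(spec.n_genes, size=nnz, replace=False)
        vals = factor_rng.standard_normal(nnz)
        vals /= np.linalg.norm(vals)
        W[support, f] = vals

    studies = []
    study_rngs = ss.spawn(spec.n_studies + 1)[1:]
    for s in range(spec.n_studies):
        rng = np.random.default_rng(study_rngs[s])
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
        X = baseline[:, None] + (spec.noise_sd * gene_scale)[:, None] * rng.standard_normal(
            (spec.n_genes, spec.n_samples)
        )
        strengths = spec.factor_strengths()
        for f, carriers in sharing.items():
            if s not in carriers:
                continue
            # per-loaded-gene sd == factor strength: scores scaled by
            # sqrt(nnz) since unit-norm loading entries are ~ 1/sqrt(nnz)
            z = rng.normal(0.0, strengths[f] * np.sqrt(nnz), size=spec.n_samples)
            X += np.outer(W[:, f], z)
        data = pd.DataFrame(
            X, index=genes, columns=[f"s{s:02d}_smp{j:03d}" for j in range(spec.n_samples)]
        )
        studies.append(ExpressionMatrix(f"study{s:02d}", data, "log"))

    truth = pd.DataFrame(W, index=genes, columns=[f"factor{f}" for f in range(spec.n_factors)])
    return studies, truth, sharing


def make_negative_controls(
    pool: pd.DataFrame,
    stats: NormalizationStats,
    n_datasets: int = 50,
    n_samples: int = 50,
    noise_range: float = 0.1,
    seed: int = 0,
) -> list[ExpressionMatrix]:
    """Gene-scrambled synthetic datasets used to calibrate the cluster count.

    Each control draws ``n_samples`` random columns from ``pool`` (the
    genes x samples concatenation of all training studies on the log
    scale), permutes the gene labels independently per control — destroying
    any shared gene-space structure while preserving each sample's value
    distribution — adds i.i.d. uniform(-noise_range, noise_range) noise,
    and row-normalises with the *pooled* per-gene mean/sd of the training
    corpus (not the control's own statistics).
    """
    if pool.shape[1] < n_samples:
        raise ValueError(
            f"pool has {pool.shape[1]} samples; need >= {n_samples}"
        )
    pool = pool.loc[stats.gene_ids]
    G = pool.shape[0]
    controls = []
    for i, sub in enumerate(np.random.SeedSequence(seed).spawn(n_datasets)):
        rng = np.random.default_rng(sub)
        cols = rng.choice(pool.shape[1], size=n_samples, replace=False)
        X = pool.to_numpy()[:, cols]
        X = X[rng.permutation(G), :]  # scramble gene labels
        X = X + rng.uniform(-noise_range, noise_range, size=X.shape)
        X = (X - stats.mean[:, None]) / stats.sd[:, None]
        data = pd.DataFrame(
            X, index=stats.gene_ids, columns=[f"nc{i:02d}_smp{j:03d}" for j in range(n_samples)]
        )
        controls.append(ExpressionMatrix(f"control{i:02d}", data, "log"))
    return controls


def make_positive_controls(
    study: ExpressionMatrix, n: int = 10, seed: int = 0
) -> list[ExpressionMatrix]:
    """Bootstrap resamples of one study (samples drawn with replacement,
    same size); their top PCs should cluster with the source study's."""
    if study.n_samples < 2:
        raise ValueError("need >= 2 samples to bootstrap")
    out = []
    for i, sub in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(sub)
        cols = rng.integers(0, study.n_samples, size=study.n_samples)
        data = study.data.iloc[:, cols].copy()
        data.columns = [f"bs{i:02d}_smp{j:03d}" for j in range(study.n_samples)]
        out.append(ExpressionMatrix(f"{study.study_id}_bs{i:02d}", data, study.scale))
    return out
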