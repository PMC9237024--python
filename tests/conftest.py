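import numpy as np
import pandas as pd
import pytest

from ravkit.containers import ExpressionMatrix
from ravkit.model import RAVModel
from ravkit.synthetic import PlantedCorpusSpec, make_planted_corpus


@pytest.fixture(scope="session")
def small_spec() -> PlantedCorpusSpec:
    return PlantedCorpusSpec(
        n_studies=10,
        n_genes=400,
        n_samples=40,
        n_factors=3,
        studies_per_factor=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return make_planted_corpus(small_spec)


@pytest.fixture(scope="session")
def study_meta(small_corpus):
    studies, _, sharing = small_corpus
    terms = {
        0: ["Colonic Neoplasms", "Humans"],
        1: ["Breast Neoplasms", "Humans"],
        2: ["Lupus Erythematosus, Systemic", "Humans"],
    }
    rows = []
    for i, s in enumerate(studies):
        mesh = ["Humans", "Gene Expression Profiling"]
        for f, carriers in sharing.items():
            if i in carriers:
                mesh += terms[f % 3]
        rows.append((s.study_id, s.n_samples, f"Synthetic study {i}", sorted(set(mesh))))
    return pd.DataFrame(
        rows, columns=["studyId", "sampleCount", "title", "meshTerms"]
    ).set_index("studyId")


@pytest.fixture(scope="session")
def fitted_model(small_corpus, study_meta) -> RAVModel:
    studies, _, _ = small_corpus
    return RAVModel(n_pcs=5).fit(studies, study_meta=study_meta)


def make_study(values, study_id="s", genes=None, samples=None, scale="log"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"smp{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(study_id, pd.DataFrame(values, index=genes, columns=samples), scale)
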