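from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ravkit import annotate

from oracles import bh_stepup_brute, gsea_es_brute, gsea_exact_null


@pytest.fixture
def toy_collection():
    return annotate.GeneSetCollection(
        {
            "HEAD": [f"g{i}" for i in range(5)],
            "TAIL": [f"g{i}" for i in range(15, 20)],
            "MIX": ["g0", "g7", "g13", "g19"],
        }
    )


@pytest.fixture
def toy_loading():
    # g0 has the largest loading, g19 the smallest (most negative)
    return pd.Series(np.linspace(2.0, -2.0, 20), index=[f"g{i}" for i in range(20)])


class TestGMT:
    def test_round_trip(self, tmp_path, toy_collection):
        p = tmp_path / "sets.gmt"
        annotate.write_gmt(toy_collection, p)
        back = annotate.read_gmt(p)
        assert back.sets == toy_collection.sets

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("OK\tdesc\tg1\tg2\nBAD_ONLY_TWO\tdesc\n")
        with pytest.raises(ValueError, match="line 2"):
            annotate.read_gmt(p)

    def test_size_filter_bounds(self):
        coll = annotate.GeneSetCollection(
            {
                "nine": [f"g{i}" for i in range(9)],
                "ten": [f"g{i}" for i in range(10)],
                "fivehundred": [f"g{i}" for i in range(500)],
                "big": [f"g{i}" for i in range(501)],
            }
        )
        kept = annotate.filter_sets(coll, 10, 500)
        assert set(kept.sets) == {"ten", "fivehundred"}


class TestEnrichmentScore:
    def test_head_set_positive_tail_set_negative(self, toy_loading, toy_collection):
        res = annotate.preranked_gsea(toy_loading, toy_collection, n_perm=50, seed=0)
        res = res.set_index("set")
        assert res.loc["HEAD", "es"] > 0.9
        assert res.loc["TAIL", "es"] < -0.9

    def test_es_bounded(self, toy_loading, toy_collection):
        res = annotate.preranked_gsea(toy_loading, toy_collection, n_perm=20, seed=1)
        assert res["es"].between(-1, 1).all()

    def test_exhaustive_matches_brute_force_enumeration(self, toy_loading):
        """ES and exact permutation p against an independent enumerator
        on a 20-gene list with a 5-gene set."""
        coll = annotate.GeneSetCollection({"S": ["g2", "g5", "g6", "g11", "g17"]})
        res = annotate.preranked_gsea(toy_loading, coll, method="exhaustive").iloc[0]
        values = np.sort(toy_loading.to_numpy())[::-1]
        mask = np.zeros(20, dtype=bool)
        mask[[2, 5, 6, 11, 17]] = True  # positions equal indices: already ranked
        es = gsea_es_brute(values, mask)
        null = gsea_exact_null(values, 5)
        p = float((np.abs(null) >= abs(es) - 1e-12).mean())
        assert res["es"] == pytest.approx(es, abs=1e-12)
        assert res["pvalue"] == pytest.approx(p, abs=1e-12)

    def test_permutation_p_reproducible(self, toy_loading, toy_collection):
        a = annotate.preranked_gsea(toy_loading, toy_collection, n_perm=100, seed=7)
        b = annotate.preranked_gsea(toy_loading, toy_collection, n_perm=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_small_sets_skipped(self, toy_loading):
        coll = annotate.GeneSetCollection({"ONE": ["g3"], "OK": ["g1", "g2", "g3"]})
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = annotate.preranked_gsea(toy_loading, coll, n_perm=10, seed=0)
        assert res["set"].tolist() == ["OK"]

    def test_agrees_with_gseapy_es(self, toy_loading):
        """Independent cross-check of the ES statistic against gseapy."""
        import gseapy

        sets = {"A": ["g0", "g3", "g8", "g12"], "B": ["g15", "g16", "g18", "g19"]}
        ours = (
            annotate.preranked_gsea(
                toy_loading, annotate.GeneSetCollection(sets), n_perm=10, seed=0
            )
            .set_index("set")["es"]
        )
        rnk = toy_loading.rename("score").rename_axis("gene").reset_index()
        res = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=10, min_size=2, max_size=50,
            seed=0, threads=1, no_plot=True, outdir=None,
        ).res2d.set_index("Term")
        for name in sets:
            assert float(res.loc[name, "ES"]) == pytest.approx(ours[name], abs=1e-6)


class TestBHAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(annotate.bh_adjust([0.3]), [0.3])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            annotate.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        np.testing.assert_allclose(annotate.bh_adjust(p), bh_stepup_brute(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_dominates_p_and_order_preserving(self, p):
        q = annotate.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            annotate.bh_adjust([0.5, 1.5])


class TestSelectEnriched:
    def _rows(self, qvals):
        return pd.DataFrame({"set": [f"s{i}" for i in range(len(qvals))],
                             "pvalue": qvals, "qvalue": qvals})

    def test_nothing_significant(self):
        assert annotate.select_enriched(self._rows([0.5, 0.5])).empty

    def test_min_q_ties_kept(self):
        kept = annotate.select_enriched(self._rows([0.01, 0.01, 0.04]))
        assert kept["set"].tolist() == ["s0", "s1"]

    def test_single_significant_row(self):
        kept = annotate.select_enriched(self._rows([0.5, 0.02]))
        assert kept["set"].tolist() == ["s1"]


class TestPathwayMetrics:
    def _model(self, table):
        return SimpleNamespace(gsea_=table)

    def test_coverage_counts_distinct_sets(self):
        coll = annotate.GeneSetCollection({f"s{i}": ["a", "b"] for i in range(10)})
        table = pd.DataFrame({"rav": ["RAV1", "RAV2", "RAV2"], "set": ["s0", "s0", "s3"],
                              "nes": [1.0, 1.0, 1.0]})
        m = self._model(table)
        assert annotate.pathway_coverage(m, coll) == pytest.approx(0.2)
        # adding an annotation can only increase coverage
        table2 = pd.concat([table, pd.DataFrame({"rav": ["RAV3"], "set": ["s5"], "nes": [2.0]})])
        assert annotate.pathway_coverage(self._model(table2), coll) >= 0.2

    def test_coverage_errors_on_empty_collection(self):
        with pytest.raises(ValueError):
            annotate.pathway_coverage(self._model(pd.DataFrame({"set": []})),
                                      annotate.GeneSetCollection({"x": ["a"]}).__class__({}))

    def test_separation_rule(self):
        table = pd.DataFrame(
            {
                "rav": ["RAV1", "RAV2", "RAV3", "RAV3"],
                "set": [
                    "RESPONSE_TYPE_I_INTERFERON",
                    "RESPONSE_TYPE_II_INTERFERON",
                    "RESPONSE_TYPE_I_INTERFERON",
                    "RESPONSE_TYPE_II_INTERFERON",
                ],
                "nes": [2.0, 2.0, 2.0, 1.5],
            }
        )
        m = self._model(table)
        sep1 = annotate.pathway_separation(m, [("ifn", "type_i_", "type_ii_")], top_n=1)
        assert bool(sep1.loc["ifn", "separated"])
        # at top_n = 2 RAV3's top list contains both sides -> not separated
        sep2 = annotate.pathway_separation(m, [("ifn", "type_i_", "type_ii_")], top_n=2)
        assert not bool(sep2.loc["ifn", "separated"])

    def test_separation_flags_unmatched_pattern(self):
        m = self._model(pd.DataFrame({"rav": ["RAV1"], "set": ["X"], "nes": [1.0]}))
        with pytest.warns(UserWarning, match="match no"):
            out = annotate.pathway_separation(m, [("none", "foo", "bar")], top_n=1)
        assert not bool(out.loc["none", "separated"])


class TestMeshScore:
    def test_hand_computed_example(self):
        members = pd.DataFrame({"study_id": ["s1", "s2"], "variance_explained": [0.5, 0.3]})
        terms = {"s1": ["A"], "s2": ["A", "B"]}
        universe = pd.Series({"A": 4.0, "B": 1.0})
        scores = annotate.mesh_score(members, terms, universe, drop_list=())
        assert scores["A"] == pytest.approx((0.5 + 0.3) / 4)
        assert "B" not in scores  # occurrence 1 <= 0.5 x cluster size 2

    def test_drop_list_absolute(self):
        members = pd.DataFrame({"study_id": ["s1", "s2"], "variance_explained": [0.5, 0.3]})
        terms = {"s1": ["A"], "s2": ["A"]}
        universe = pd.Series({"A": 1.0})
        scores = annotate.mesh_score(members, terms, universe, drop_list=("A",))
        assert scores.empty

    def test_large_cluster_count_threshold(self):
        members = pd.DataFrame(
            {"study_id": [f"s{i}" for i in range(8)], "variance_explained": [0.1] * 8}
        )
        # term FOUR on 4 member PCs (eliminated), FIVE on 5 (kept)
        terms = {f"s{i}": (["FOUR"] if i < 4 else []) + (["FIVE"] if i < 5 else [])
                 for i in range(8)}
        universe = pd.Series({"FOUR": 10.0, "FIVE": 10.0})
        scores = annotate.mesh_score(members, terms, universe, drop_list=())
        assert "FOUR" not in scores
        assert scores["FIVE"] == pytest.approx(0.5 / 10)

    def test_score_halves_when_universe_frequency_doubles(self):
        members = pd.DataFrame({"study_id": ["s1", "s2", "s3"], "variance_explained": [0.2] * 3})
        terms = {s: ["T"] for s in ["s1", "s2", "s3"]}
        s1 = annotate.mesh_score(members, terms, pd.Series({"T": 2.0}), drop_list=())
        s2 = annotate.mesh_score(members, terms, pd.Series({"T": 4.0}), drop_list=())
        assert s1["T"] == pytest.approx(2 * s2["T"])

    def test_missing_metadata_errors(self):
        members = pd.DataFrame({"study_id": ["s1", "s2"], "variance_explained": [0.5, 0.5]})
        with pytest.raises(KeyError, match="s2"):
            annotate.mesh_score(members, {"s1": ["A"]}, pd.Series({"A": 1.0}), drop_list=())

    def test_universe_counts_with_multiplicity(self):
        prov = pd.DataFrame(
            {"study_id": ["s1", "s1", "s2", "c"], "is_control": [False, False, False, True]}
        )
        uni = annotate.mesh_universe(prov, {"s1": ["A"], "s2": ["A", "B"], "c": ["A"]})
        assert uni["A"] == 3.0  # two PCs of s1 + one of s2; control excluded
        assert uni["B"] == 1.0


class TestAnnotateModel:
    def test_fitted_model_annotation(self, fitted_model, small_corpus):
        _, truth, _ = small_corpus
        genes = fitted_model.rav_index_.gene_ids
        sets = {}
        for f in truth.columns:
            # sign-coherent program: genes with the largest positive loadings,
            # so they concentrate at one end of the signed ranking
            top = truth.loc[genes, f].nlargest(20).index.tolist()
            sets[f"PROGRAM_{f.upper()}"] = top
        rng = np.random.default_rng(0)
        sets["RANDOM"] = list(rng.choice(genes, size=20, replace=False))
        coll = annotate.GeneSetCollection(sets)
        table = fitted_model.annotate_gsea(coll, n_perm=200, seed=3)
        assert set(table.columns) >= {"rav", "set", "es", "nes", "pvalue", "qvalue"}
        # each planted program should annotate at least one RAV
        for f in truth.columns:
            assert (table["set"] == f"PROGRAM_{f.upper()}").any()
        cov = annotate.pathway_coverage(fitted_model, coll)
        assert 0 < cov <= 1

    def test_mesh_annotation_on_model(self, fitted_model):
        table = fitted_model.annotate_mesh()
        assert set(table.columns) == {"rav", "term", "score"}
        assert (table["score"] > 0).all()
        # drop-list terms never appear
        assert not table["term"].isin(annotate.DEFAULT_DROP_LIST).any()
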