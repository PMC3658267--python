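"""Naive-Bayes refinement: features, LLR training, L-scores, p-values."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosmap.bayes import (Annotations, FEATURES, KSRBayesRefiner, combine,
                           compute_features, cross_validate, empirical_p,
                           l_score, l_scores, rank_edges, refine, train)
from phosmap.simulate import simulate_pair_features
from phosmap.types import KSREdge


@pytest.fixture
def annotations():
    expr = pd.DataFrame(
        {"T1": [1.0, 1.0, 0.0, np.nan],
         "T2": [2.0, 2.0, 1.0, np.nan],
         "T3": [3.0, 3.0, 0.5, 1.0],
         "T4": [4.0, 4.0, 2.0, 2.0]},
        index=["K1", "S_same", "S_other", "S_sparse"])
    comp = {"K1": {"nucleus"}, "S_same": {"nucleus", "cytosol"},
            "S_other": {"cytosol"}}
    g = nx.Graph([("K1", "X"), ("X", "S_other"), ("K1", "S_same")])
    return Annotations(expr, comp, g)


class TestComputeFeatures:
    def test_identical_expression_gives_unit_correlation(self, annotations):
        f = compute_features("K1", "S_same", annotations)
        assert f.tissue_coexpr == pytest.approx(1.0)

    def test_disjoint_compartments(self, annotations):
        assert compute_features("K1", "S_other", annotations).coloc == 0

    def test_shared_compartment(self, annotations):
        assert compute_features("K1", "S_same", annotations).coloc == 1

    def test_shared_neighbor_counts_as_ppi(self, annotations):
        # K1-X and X-S_other, no direct K1-S_other edge
        f = compute_features("K1", "S_other", annotations)
        assert f.ppi == 1

    def test_direct_edge(self, annotations):
        assert compute_features("K1", "S_same", annotations).ppi == 1

    def test_missing_when_annotation_absent(self, annotations):
        f = compute_features("K1", "S_sparse", annotations)
        assert f.tissue_coexpr is None  # only 2 shared measured tissues
        assert f.coloc is None and f.ppi is None

    def test_missing_for_unknown_protein(self, annotations):
        f = compute_features("K1", "UNSEEN", annotations)
        assert f.tissue_coexpr is None and f.coloc is None and f.ppi is None


class TestTrain:
    def test_bin_probabilities_sum_to_one(self, rng):
        pos, neg = simulate_pair_features(200, 500, rng=rng)
        model = train(pos, neg)
        for f in FEATURES:
            p_pos, p_neg = model.probs[f]
            assert p_pos.sum() == pytest.approx(1.0, abs=1e-9)
            assert p_neg.sum() == pytest.approx(1.0, abs=1e-9)

    def test_binary_feature_llr_closed_form(self, rng):
        # coloc present in 80% of positives, 20% of negatives; at large n
        # the pseudocount washes out and llr(1) -> log2(4) = 2
        n = 20000
        pos = pd.DataFrame({"tissue_coexpr": np.nan, "ppi": np.nan,
                            "coloc": (rng.random(n) < 0.8).astype(float)},
                           index=range(n))
        neg = pd.DataFrame({"tissue_coexpr": np.nan, "ppi": np.nan,
                            "coloc": (rng.random(n) < 0.2).astype(float)},
                           index=range(n))
        model = train(pos, neg)
        assert model.llr["coloc"][1] == pytest.approx(2.0, abs=0.08)
        assert model.llr["coloc"][0] == pytest.approx(-2.0, abs=0.08)

    def test_equal_distributions_give_near_zero_llr(self, rng):
        pos, neg = simulate_pair_features(5000, 5000, uninformative=True,
                                          rng=rng)
        model = train(pos, neg)
        for f in FEATURES:
            # common bins only; rare bins are noisier
            mask = model.probs[f][1] > 0.05
            assert np.all(np.abs(model.llr[f][mask]) < 0.35)

    def test_degenerate_feature_zeroed_with_warning(self):
        pos = pd.DataFrame({"tissue_coexpr": [0.5] * 20,
                            "coloc": [1.0] * 20, "ppi": [0.0] * 20})
        neg = pd.DataFrame({"tissue_coexpr": [0.5] * 30,
                            "coloc": [1.0] * 30, "ppi": [1.0] * 30})
        with pytest.warns(UserWarning, match="degenerate"):
            model = train(pos, neg)
        assert np.all(model.llr["coloc"] == 0.0)
        assert not np.all(model.llr["ppi"] == 0.0)

    def test_minimum_training_sizes(self):
        tiny = pd.DataFrame({f: [0.0] * 5 for f in FEATURES})
        with pytest.raises(ValueError, match=">= 10"):
            train(tiny, tiny)


class TestLScore:
    def test_additive_over_features(self, rng):
        pos, neg = simulate_pair_features(500, 2000, rng=rng)
        model = train(pos, neg)
        probe = neg.iloc[:50]
        total = l_scores(probe, model)
        # independent summation oracle: score each feature alone by
        # blanking the other two (missing contributes the missing-bin llr)
        parts = np.zeros(len(probe))
        missing_sum = sum(model.llr[f][-1] for f in FEATURES)
        for f in FEATURES:
            solo = pd.DataFrame(
                {g: probe[g] if g == f else np.nan for g in FEATURES})
            parts += l_scores(solo, model)
        # each solo frame adds the other two features' missing-bin llrs
        np.testing.assert_allclose(total, parts - 2 * missing_sum,
                                   atol=1e-9)

    def test_zero_llr_bins_give_zero_score(self):
        pos = pd.DataFrame({"tissue_coexpr": [0.5] * 20,
                            "coloc": [1.0] * 20, "ppi": [1.0] * 20})
        with pytest.warns(UserWarning, match="degenerate"):
            model = train(pos, pos.copy())
        assert l_scores(pos, model) == pytest.approx(np.zeros(20))

    def test_single_pair_matches_batch(self, rng):
        pos, neg = simulate_pair_features(200, 800, rng=rng)
        model = train(pos, neg)
        from phosmap.bayes import PairFeatures
        f = PairFeatures(tissue_coexpr=0.7, coloc=1, ppi=None)
        row = pd.DataFrame([f.as_row()])
        assert l_score(f, model) == pytest.approx(
            float(l_scores(row, model)[0]))


class TestEmpiricalP:
    @pytest.fixture
    def model(self, rng):
        pos, neg = simulate_pair_features(300, 2000, rng=rng)
        return train(pos, neg)

    def test_bounds(self, model):
        n = model.neg_scores.size
        below = model.neg_scores.min() - 10
        above = model.neg_scores.max() + 10
        assert empirical_p(below, model)[0] == pytest.approx(1.0)
        assert empirical_p(above, model)[0] == pytest.approx(1 / (n + 1))

    def test_negative_scores_are_super_uniform(self, model):
        p = empirical_p(model.neg_scores, model)
        n = len(p)
        grid = np.linspace(0.01, 1.0, 25)
        ecdf = np.array([(p <= u).mean() for u in grid])
        assert np.all(ecdf <= grid + 1.0 / n + 1e-12)


def _benchmark_edges(n_true=200, n_rand=800):
    true = [KSREdge(f"K{i % 10}", f"T{i}", "raw", array_z=4.0)
            for i in range(n_true)]
    rand = [KSREdge(f"K{i % 10}", f"R{i}", "raw", array_z=3.5)
            for i in range(n_rand)]
    return true, rand


class TestRefineCombine:
    def _refined(self, rng, alpha=0.05):
        pos, neg = simulate_pair_features(1103, 10000, rng=rng)
        model = train(pos, neg)
        true_f, rand_f = simulate_pair_features(200, 800, rng=rng)
        feats = pd.concat([true_f, rand_f], ignore_index=True)
        p = empirical_p(l_scores(feats, model), model)
        return p

    def test_refined_precision_beats_raw(self, rng):
        p = self._refined(rng)
        sel = p < 0.05
        assert sel.sum() > 0
        precision_ref = sel[:200].sum() / sel.sum()
        assert precision_ref > 200 / 1000  # raw precision by construction

    def test_refined_count_monotone_in_alpha(self, rng):
        p = self._refined(rng)
        counts = [(p < a).sum() for a in (0.01, 0.05, 0.1, 0.5)]
        assert counts == sorted(counts)

    def test_combine_disjoint_union(self):
        ref = [KSREdge("K1", "A", "refined", l_score=1.0, p_value=0.01)]
        known = [KSREdge("K2", "B", "known")]
        com = combine(ref, known)
        assert len(com) == 2
        assert {e.stage for e in com} == {"refined", "known"}

    def test_combine_overlap_known_wins_and_flagged(self):
        ref = [KSREdge("K1", "A", "refined", l_score=1.0, p_value=0.01)]
        known = [KSREdge("K1", "A", "known")]
        com = combine(ref, known)
        assert len(com) == 1
        assert com[0].stage == "known" and com[0].known_overlap
        assert com[0].p_value == pytest.approx(0.01)


class TestCrossValidate:
    def test_planted_benchmark_enrichment(self, default_sim):
        """Known KSRs held out fold-wise are recovered far above chance."""
        sim = default_sim
        truth = sorted(sim.ground_truth.true_ksr)
        rng = np.random.default_rng(1)
        known = [KSREdge(k, s, "known") for k, s in truth]
        rand_idx = rng.choice(len(sim.proteome), size=400)
        prot_ids = sorted(sim.proteome)
        kinases = sorted({k for k, _ in truth})
        raw = [KSREdge(k, s, "raw") for k, s in truth]
        raw += [KSREdge(kinases[i % len(kinases)], prot_ids[j], "raw")
                for i, j in enumerate(rand_idx)
                if (kinases[i % len(kinases)], prot_ids[j])
                not in sim.ground_truth.true_ksr]
        pool = [(prot_ids[i], prot_ids[j])
                for i, j in zip(rng.choice(len(prot_ids), 500),
                                rng.choice(len(prot_ids), 500)) if i != j]
        enrichment = cross_validate(known, raw, sim.annotations, pool,
                                    k_folds=5, rng=rng)
        assert enrichment > 2.0

    def test_too_few_folds_or_positives(self, default_sim):
        known = [KSREdge("K01", "P0001", "known")]
        with pytest.raises(ValueError):
            cross_validate(known, [], default_sim.annotations, [("a", "b")],
                           k_folds=1)
        with pytest.raises(ValueError, match="fewer positives"):
            cross_validate(known, [], default_sim.annotations, [("a", "b")],
                           k_folds=5)


class TestEstimator:
    def test_fit_predict_roundtrip(self, rng):
        pos, neg = simulate_pair_features(300, 3000, rng=rng)
        X = pd.concat([pos, neg], ignore_index=True)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        clf = KSRBayesRefiner(alpha=0.05).fit(X, y)
        L = clf.decision_function(pos)
        assert L.mean() > clf.decision_function(neg).mean()
        yhat = clf.predict(X)
        assert set(np.unique(yhat)) <= {0, 1}
        # positives should be selected far more often than negatives
        assert yhat[: len(pos)].mean() > 4 * max(yhat[len(pos):].mean(),
                                                 1e-3)

    def test_sklearn_protocol(self):
        from sklearn.base import clone
        clf = KSRBayesRefiner(n_bins=7, alpha=0.1)
        assert clone(clf).get_params()["n_bins"] == 7
        with pytest.raises(ValueError, match="not fitted"):
            clf.decision_function(pd.DataFrame(
                {f: [0.0] for f in FEATURES}))
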