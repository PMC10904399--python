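"""Consensus rank aggregation, odds/activity features, constrained logistic
fusion, balanced metrics, recall evaluation."""

import numpy as np
import pandas as pd
import pytest

import funcsig as fs


def clist(compound, genes_probs, **kw):
    return fs.CandidateList(compound, list(genes_probs), **kw)


class TestConsensusAggregate:
    def test_hand_pooled_example(self):
        # list1 (n=4): g2,g1,g3,g4; list2 (n=2): g1,g5
        l1 = clist("c", [("g2", 0.9), ("g1", 0.8), ("g3", 0.7), ("g4", 0.6)])
        l2 = clist("c", [("g1", 0.95), ("g5", 0.1)])
        cons = fs.consensus_aggregate([l1, l2])
        assert cons.entries == [("g2", 0.25), ("g1", 0.5), ("g3", 0.75),
                                ("g4", 1.0), ("g5", 1.0)]
        # g4 before g5 purely by gene-id tie-break at rank 1.0
        assert [g for g, _ in cons.entries].index("g4") < \
            [g for g, _ in cons.entries].index("g5")

    def test_single_list_is_identity(self):
        l1 = clist("c", [("a", 0.9), ("b", 0.5), ("c", 0.1)])
        cons = fs.consensus_aggregate([l1])
        assert [g for g, _ in cons.entries] == ["a", "b", "c"]

    def test_duplicate_keeps_best_rank(self):
        l1 = clist("c", [("a", 0.9), ("b", 0.5)])
        l2 = clist("c", [("b", 0.9), ("a", 0.5)])
        cons = fs.consensus_aggregate([l1, l2])
        assert dict(cons.entries) == {"a": 0.5, "b": 0.5}

    def test_equals_min_normalized_rank_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        for trial in range(10):
            lists = []
            for li in range(rng.integers(1, 5)):
                chosen = rng.choice(genes, size=rng.integers(3, 20),
                                    replace=False)
                lists.append(clist("c", [(g, float(rng.random()))
                                         for g in chosen]))
            cons = fs.consensus_aggregate(lists)
            # oracle: per gene, minimum normalized rank across lists
            oracle: dict[str, float] = {}
            for cl in lists:
                for g, r in cl.normalized_ranks():
                    oracle[g] = min(oracle.get(g, 2.0), r)
            assert dict(cons.entries) == pytest.approx(oracle)
            ranks = [r for _, r in cons.entries]
            assert ranks == sorted(ranks)

    def test_ties_broken_by_gene_id_within_a_list(self):
        cl = clist("c", [("z", 0.5), ("a", 0.5), ("m", 0.5)])
        assert [g for g, _ in cl.entries] == ["a", "m", "z"]

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ValueError):
            fs.consensus_aggregate([clist("c1", [("a", 1)]),
                                    clist("c2", [("a", 1)])])


class TestFeatures:
    @pytest.mark.parametrize("r,expected", [(0.5, 1.0), (0.05, 19.0),
                                            (1.0, 0.0)])
    def test_odds_ratio(self, r, expected):
        assert fs.odds_ratio_feature(r) == pytest.approx(expected)

    def test_odds_ratio_rejects_nonpositive_rank(self):
        with pytest.raises(ValueError):
            fs.odds_ratio_feature(0.0)

    def test_logit_features_clip(self):
        x = fs.logit_features(np.array([0.0, 0.5, 1.0]))
        assert np.isfinite(x).all()
        assert x[1] == pytest.approx(0.0)

    def test_max_profile_correlation(self):
        values = pd.DataFrame(
            {"a1": [1.0, 2.0, 1.0, -1.0], "a2": [2.0, 4.0, 0.0, -2.0],
             "a3": [3.0, 6.0, -1.0, -3.0]},
            index=["query", "twin", "noisy", "anti"]).T.T
        mat = fs.ActivityMatrix(values,
                                {"tg": ["twin", "noisy", "anti"]})
        # identical profile present -> max q = 1
        assert fs.max_profile_correlation("query", "tg", mat) == \
            pytest.approx(1.0)
        anti = fs.ActivityMatrix(values, {"tg": ["anti"]})
        assert fs.max_profile_correlation("query", "tg", anti) == \
            pytest.approx(-1.0)

    def test_missing_references_flagged_as_nan(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["query"],
                              columns=["a", "b", "c"])
        mat = fs.ActivityMatrix(values, {})
        assert np.isnan(fs.max_profile_correlation("query", "tg", mat))

    def test_insufficient_shared_assays_flagged(self):
        values = pd.DataFrame([[1.0, np.nan, np.nan],
                               [np.nan, 1.0, 2.0]],
                              index=["query", "ref"],
                              columns=["a", "b", "c"])
        mat = fs.ActivityMatrix(values, {"tg": ["ref"]})
        assert np.isnan(fs.max_profile_correlation("query", "tg", mat))


class TestNonNegativeLogistic:
    def test_separable_positive_signal(self):
        X = np.array([[0.], [1.], [2.], [3.], [10.], [11.], [12.], [13.]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = fs.lr_fit(X, y, lambda_grid=[1e-3])
        assert model.coef_[0] > 0
        assert (model.predict(X) == y).all()

    def test_anti_predictive_feature_driven_to_zero(self):
        # signal points negative: the constraint forces w = 0, and under
        # class weighting the intercept settles near the balanced prior 0.5
        X = np.array([[10.], [11.], [12.], [13.], [0.], [1.], [2.], [3.]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = fs.lr_fit(X, y, lambda_grid=[1e-3])
        assert model.coef_[0] == pytest.approx(0.0, abs=1e-6)
        p = fs.lr_predict(model, np.array([5.0]))
        assert p == pytest.approx(0.5, abs=0.05)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        m1 = fs.lr_fit(X, y, lambda_grid=[1.0])
        m2 = fs.lr_fit(np.vstack([X, X]), np.concatenate([y, y]),
                       lambda_grid=[1.0])
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-6)
        assert m1.intercept_ == pytest.approx(m2.intercept_, abs=1e-6)

    def test_weights_nonnegative_and_predictions_monotone(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            X = rng.normal(size=(60, 3))
            y = (rng.random(60) < 0.3).astype(int)
            if len(np.unique(y)) < 2:
                continue
            model = fs.lr_fit(X, y, seed=trial)
            assert (model.coef_ >= -1e-12).all()
            x0 = rng.normal(size=3)
            p0 = fs.lr_predict(model, x0)
            for j in range(3):
                bumped = x0.copy()
                bumped[j] += 1.0
                assert fs.lr_predict(model, bumped) >= p0 - 1e-12

    def test_all_zero_features_yield_intercept_model(self):
        X = np.zeros((10, 2))
        y = np.array([0, 1] * 5)
        with pytest.warns(UserWarning, match="intercept-only"):
            model = fs.NonNegativeLogisticRegression().fit(X, y)
        assert np.allclose(model.coef_, 0.0)

    def test_inner_cv_selects_lambda_from_grid(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 1))
        y = (X[:, 0] > 0).astype(int)
        grid = [1e-3, 1e3]
        model = fs.NonNegativeLogisticRegression(grid, random_state=0).fit(X, y)
        assert model.lambda_ in grid
        assert model.lambda_ == 1e-3  # heavy shrinkage loses on separable data

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fs.lr_fit(np.ones((4, 1)), [1, 1, 1, 1])


class TestBalancedMetrics:
    def test_weighted_count_arithmetic(self):
        m = fs.balanced_metrics(tp=1, fn=1, fp=49, tn=49, n_p=2, n_n=98)
        assert m["precision"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(0.5)

    def test_balanced_classes_reduce_to_plain_metrics(self):
        tp, fp, tn, fn = 30, 10, 40, 20
        m = fs.balanced_metrics(tp, fp, tn, fn, n_p=50, n_n=50)
        plain_precision = tp / (tp + fp)
        plain_recall = tp / (tp + fn)
        assert m["precision"] == pytest.approx(plain_precision)
        assert m["recall"] == pytest.approx(plain_recall)

    def test_perfect_classifier(self):
        m = fs.balanced_metrics(tp=5, fp=0, tn=95, fn=0, n_p=5, n_n=95)
        assert m["precision"] == m["recall"] == m["f1"] == 1.0
        assert m["mcc"] == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            fs.balanced_metrics(0, 0, 0, 0, n_p=0, n_n=5)

    def test_weighted_curve_areas_on_balanced_data_match_plain(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 50)
        s = y + rng.normal(scale=0.8, size=100)
        areas = fs.weighted_curve_areas(y, s)
        assert areas["roc_auc"] == pytest.approx(roc_auc_score(y, s))


class TestRecallAtPercent:
    def make_ranking(self, compound, ordered_genes):
        n = len(ordered_genes)
        return fs.ConsensusRanking(compound,
                                   [(g, (i + 1) / n)
                                    for i, g in enumerate(ordered_genes)])

    def test_top_ranked_target_always_recalled(self):
        genes = [f"g{i}" for i in range(100)]
        rankings = {"c": self.make_ranking("c", genes)}
        assert fs.recall_at_percent(rankings, {"c": {"g0"}}) == 1.0

    def test_strict_boundary(self):
        ranking = fs.ConsensusRanking("c", [("a", 0.05), ("b", 0.051)])
        rankings = {"c": ranking}
        assert fs.recall_at_percent(rankings, {"c": {"a"}}, 5.0) == 1.0
        assert fs.recall_at_percent(rankings, {"c": {"b"}}, 5.0) == 0.0

    def test_uniform_random_null_near_five_percent(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        rankings, known = {}, {}
        for ci in range(200):
            order = list(rng.permutation(genes))
            rankings[f"c{ci}"] = self.make_ranking(f"c{ci}", order)
            known[f"c{ci}"] = {genes[0]}
        recall = fs.recall_at_percent(rankings, known, 5.0)
        assert abs(recall - 0.05) < 0.05  # binomial 3-sigma comfort band

    def test_missing_compounds_excluded(self, caplog):
        rankings = {"c1": self.make_ranking("c1", ["a", "b"])}
        with caplog.at_level("INFO", logger="funcsig.ranking"):
            recall = fs.recall_at_percent(rankings,
                                          {"c1": {"a"}, "c2": {"a"}}, 50.0)
        assert recall == 1.0
        assert any("excluded" in r.message for r in caplog.records)


class TestNetworkExport:
    def test_thresholds_and_summary(self, tmp_path):
        df = pd.DataFrame({
            "compound_id": ["c1", "c1", "c2"],
            "target_gene": ["t1", "t2", "t1"],
            "probability": [0.9, 0.95, 0.7],
            "normalized_rank": [0.01, 0.2, 0.01]})
        path = tmp_path / "network.tsv"
        summary = fs.export_network(df, path)
        kept = pd.read_csv(path, sep="\t")
        # only the high-probability, top-5% edge survives
        assert len(kept) == summary["n_edges"] == 1
        assert kept.iloc[0].compound_id == "c1"
        assert (tmp_path / "network.tsv.json").exists()
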