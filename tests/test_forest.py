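import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from readmit_rsf.forest import (
    CHFStepFunction,
    ForestConfig,
    SurvivalForest,
    SurvivalForestResults,
    best_split,
    forward_feature_selection,
    grow_tree,
    logrank_statistic,
    terminal_chf,
)


class TestLogrankStatistic:
    def test_hand_worked_four_sample_node(self):
        # numerator (1-2/4)+(0-1/3)+(1-1/2)+0, denominator .25+.2222+.25+0
        sc = logrank_statistic([1, 2, 3, 4], [1, 1, 1, 1],
                               [0.2, 0.8, 0.3, 0.9], 0.5)
        assert sc.F == pytest.approx(0.6667 / np.sqrt(0.7222), abs=1e-4)
        assert sc.F == pytest.approx(0.7845, abs=1e-4)

    def test_empty_daughter_is_invalid(self):
        assert logrank_statistic([1, 2], [1, 1], [0.1, 0.2], 0.05) is None
        assert logrank_statistic([1, 2], [1, 1], [0.1, 0.2], 0.9) is None

    def test_no_events_is_invalid(self):
        assert logrank_statistic([1, 2], [0, 0], [0.1, 0.9], 0.5) is None

    def test_squared_statistic_matches_reference_logrank(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 30:
            n = int(rng.integers(4, 50))
            t = rng.integers(1, 20, n).astype(float)
            e = rng.integers(0, 2, n)
            x = rng.random(n)
            c = float(np.quantile(x, rng.uniform(0.2, 0.8)))
            sc = logrank_statistic(t, e, x, c)
            if sc is None:
                continue
            g1 = x <= c
            ref = logrank_test(t[g1], t[~g1], e[g1], e[~g1]).test_statistic
            assert sc.F ** 2 == pytest.approx(ref, abs=1e-8)
            checked += 1


class TestBestSplit:
    def test_constant_features_give_no_split(self):
        X = np.ones((5, 2))
        assert best_split([1, 2, 3, 4, 5], [1, 1, 0, 1, 0], X,
                          ["a", "b"]) is None

    def test_perfectly_separating_feature_is_chosen(self):
        # x0 splits early events from late survivors exactly
        t = np.array([1, 1, 2, 20, 25, 30], dtype=float)
        e = np.array([1, 1, 1, 0, 0, 0])
        X = np.column_stack([[1, 1, 1, 0, 0, 0],
                             [0.3, 0.9, 0.1, 0.7, 0.2, 0.8]])
        sc = best_split(t, e, X, ["early", "noise"])
        assert sc.feature == "early"
        assert sc.c == pytest.approx(0.5)

    def test_tree_splits_match_bruteforce_enumeration(self, toy_survival):
        t, e, X = toy_survival
        names = [f"x{j}" for j in range(X.shape[1])]
        cfg = ForestConfig(ntree=1, mtry=X.shape[1], nodesize_min=1, seed=0)
        tree = grow_tree(t, e, X, names, cfg)

        def walk(node, idx):
            if tree.feature[node] < 0:
                return
            ref = best_split(t[idx], e[idx], X[idx], names)
            assert ref is not None
            assert names[tree.feature[node]] == ref.feature
            assert tree.threshold[node] == pytest.approx(ref.c)
            mask = X[idx, tree.feature[node]] <= tree.threshold[node]
            walk(tree.left[node], idx[mask])
            walk(tree.right[node], idx[~mask])

        walk(0, np.arange(len(t)))


class TestTerminalCHF:
    def test_single_event_jumps_to_one(self):
        chf = terminal_chf([5], [1])
        assert chf(4.9) == 0.0
        assert chf(5) == 1.0

    def test_hand_worked_nelson_aalen(self):
        chf = terminal_chf([2, 3, 5], [1, 0, 1])
        assert chf(2) == pytest.approx(1 / 3)
        assert chf(5) == pytest.approx(4 / 3)

    def test_all_censored_gives_zero_hazard(self):
        chf = terminal_chf([2, 3, 5], [0, 0, 0])
        assert chf(10) == 0.0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            terminal_chf([], [])

    def test_neg_log_km_is_finite_and_monotone(self):
        chf = terminal_chf([1, 2, 3], [1, 1, 1], estimator="neg-log-km")
        vals = chf([1, 2, 3, 10])
        assert np.all(np.isfinite(vals))
        assert np.all(np.diff(vals) >= 0)


class TestTreeGrowth:
    def test_single_sample_is_terminal(self):
        tree = grow_tree([5.0], [1], np.array([[1.0]]), ["a"])
        assert tree.feature[0] == -1

    def test_stump_limit_equals_whole_sample_hazard(self, toy_survival):
        t, e, X = toy_survival
        cfg = ForestConfig(ntree=1, nodesize_min=len(t) + 1)
        tree = grow_tree(t, e, X, list("abcd"), cfg)
        whole = terminal_chf(t, e)
        assert tree.chf_at(X[:3], 30.0) == pytest.approx(whole(30.0))

    def test_monotone_feature_transform_leaves_structure_invariant(
            self, toy_survival):
        t, e, X = toy_survival
        cfg = ForestConfig(ntree=1, mtry=4, nodesize_min=3, seed=5)
        names = list("abcd")
        t1 = grow_tree(t, e, X, names, cfg,
                       rng=np.random.default_rng(3))
        t2 = grow_tree(t, e, np.exp(X), names, cfg,
                       rng=np.random.default_rng(3))
        assert np.array_equal(t1.feature, t2.feature)
        assert t1.chf_at(X, 30.0) == pytest.approx(
            t2.chf_at(np.exp(X), 30.0))


class TestForest:
    def test_same_seed_reproduces_predictions(self, toy_survival):
        t, e, X = toy_survival
        cfg = ForestConfig(ntree=10, seed=2)
        r1 = SurvivalForest(t, e, X, config=cfg).fit()
        r2 = SurvivalForest(t, e, X, config=ForestConfig(ntree=10,
                                                         seed=2)).fit()
        assert np.array_equal(r1.predict_risk(X), r2.predict_risk(X))

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            SurvivalForest([1, 2], [0, 0], np.ones((2, 1))).fit()

    def test_single_tree_no_bootstrap_reduces_to_grow_tree(
            self, toy_survival):
        t, e, X = toy_survival
        cfg = ForestConfig(ntree=1, bootstrap=False, seed=0, mtry=4,
                           nodesize_min=3)
        res = SurvivalForest(t, e, X, config=cfg).fit()
        assert len(res.trees) == 1
        # the ensemble of one tree is that tree's leaf hazard
        assert res.predict_chf(X, 30.0) == pytest.approx(
            res.trees[0].chf_at(X, 30.0))

    def test_hand_built_stumps_average_arithmetically(self):
        def stump(h30):
            return {"feature": [-1], "threshold": [None], "left": [-1],
                    "right": [-1], "chf_off": [0], "chf_len": [1],
                    "chf_times": [10.0], "chf_H": [h30], "n_node": [1]}
        doc = {"feature_names": ["a"],
               "config": {"ntree": 3, "mtry": None, "nodesize_min": 3,
                          "seed": 0, "horizon_days": 30, "bootstrap": True,
                          "chf_estimator": "nelson-aalen"},
               "trees": [stump(0.1), stump(0.2), stump(0.6)]}
        res = SurvivalForestResults.from_dict(doc)
        assert res.ensemble_chf([0.0], 30.0) == pytest.approx(0.3)

    def test_predicted_hazard_is_monotone_in_time(self, toy_survival):
        t, e, X = toy_survival
        res = SurvivalForest(t, e, X, config=ForestConfig(ntree=5,
                                                          seed=1)).fit()
        grid = np.arange(0, 31)
        H = np.column_stack([res.predict_chf(X, g) for g in grid])
        assert np.all(H >= 0)
        assert np.all(np.diff(H, axis=1) >= -1e-12)

    def test_ensemble_variance_shrinks_with_more_trees(self):
        rng = np.random.default_rng(0)
        n = 200
        X = rng.standard_normal((n, 5))
        p = 1 / (1 + np.exp(-(np.log(0.05 / 0.95) + X[:, 0])))
        t = np.minimum(rng.geometric(p), 30).astype(float)
        e = (t < 30).astype(int)
        probe = X[:20]
        var = {}
        for ntree in (10, 200):
            preds = []
            for seed in range(5):
                res = SurvivalForest(
                    t, e, X, config=ForestConfig(ntree=ntree,
                                                 seed=seed)).fit()
                preds.append(res.predict_risk(probe))
            var[ntree] = np.var(np.stack(preds), axis=0).mean()
        assert var[200] < var[10]

    def test_serialization_round_trip(self, toy_survival, tmp_path):
        t, e, X = toy_survival
        res = SurvivalForest(t, e, X, config=ForestConfig(ntree=3,
                                                          seed=4)).fit()
        path = tmp_path / "model.json"
        res.save(path)
        back = SurvivalForestResults.load(path)
        assert np.allclose(back.predict_risk(X), res.predict_risk(X))

    def test_summary_reports_dimensions(self, toy_survival):
        t, e, X = toy_survival
        res = SurvivalForest(t, e, X, config=ForestConfig(ntree=3,
                                                          seed=4)).fit()
        text = res.summary()
        assert "Trees:" in text and "60" in text


class TestPermutationImportance:
    def test_unused_feature_has_exactly_zero_importance(self, toy_survival):
        t, e, X = toy_survival
        Xc = np.column_stack([X, np.full(len(t), 7.0)])  # constant: unused
        names = ["a", "b", "c", "d", "const"]
        res = SurvivalForest(t, e, pd.DataFrame(Xc, columns=names),
                             config=ForestConfig(ntree=5, seed=0)).fit()
        imp = res.permutation_importance(
            pd.DataFrame(Xc, columns=names), (t <= 30) & (e == 1), seed=0)
        assert imp["const"] == 0.0

    def test_planted_signal_outranks_noise(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            X = rng.standard_normal((n, 11))
            p = 1 / (1 + np.exp(-(np.log(0.03 / 0.97) + 1.2 * X[:, 0])))
            t = np.minimum(rng.geometric(p), 30).astype(float)
            e = (t < 30).astype(int)
            res = SurvivalForest(
                t, e, X, config=ForestConfig(ntree=30, seed=seed)).fit()
            imp = res.permutation_importance(X, e, seed=seed)
            wins += imp.idxmax() == "x0"
        assert wins >= 8

    def test_duplicated_feature_shares_credit(self):
        deltas = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n = 300
            sig = rng.standard_normal(n)
            noise = rng.standard_normal((n, 3))
            p = 1 / (1 + np.exp(-(np.log(0.03 / 0.97) + 1.5 * sig)))
            t = np.minimum(rng.geometric(p), 30).astype(float)
            e = (t < 30).astype(int)
            cfg = ForestConfig(ntree=30, seed=seed)
            solo = SurvivalForest(
                t, e, np.column_stack([sig, noise]), config=cfg).fit()
            imp_solo = solo.permutation_importance(
                np.column_stack([sig, noise]), e, seed=seed)["x0"]
            dup = SurvivalForest(
                t, e, np.column_stack([sig, sig, noise]), config=cfg).fit()
            imp_dup = dup.permutation_importance(
                np.column_stack([sig, sig, noise]), e, seed=seed)
            deltas.append((imp_solo, imp_dup["x0"], imp_dup["x1"]))
        solo_m = np.mean([d[0] for d in deltas])
        dup_m = np.mean([(d[1] + d[2]) / 2 for d in deltas])
        assert dup_m < solo_m          # shared credit
        assert dup_m > -1e-6           # but still non-negative on average


class TestForwardSelection:
    def test_ten_or_fewer_features_returned_as_is(self):
        imp = pd.Series({f"f{j}": 10 - j for j in range(8)})
        assert set(forward_feature_selection(imp, lambda s: 0.0)) == set(
            imp.index)

    def test_infinite_tolerance_keeps_initial_top_ten(self):
        imp = pd.Series({f"f{j:02d}": 50 - j for j in range(50)})
        got = forward_feature_selection(imp, lambda s: len(s) / 50.0,
                                        tol=np.inf)
        assert got == [f"f{j:02d}" for j in range(10)]

    def test_improving_eval_extends_the_set(self):
        imp = pd.Series({f"f{j:02d}": 50 - j for j in range(30)})
        got = forward_feature_selection(imp, lambda s: len(s), tol=1e-3,
                                        batch_size=5)
        assert len(got) == 30
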