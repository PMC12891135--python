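"""Cancer-score model: CV training, scoring, ROC, operating points, subgroups."""

import numpy as np
import pandas as pd
import pytest

import plasmafrag as pf

import oracles


def _toy_matrix(n_per_class=20, n_features=10, effect=2.0, seed=0, metadata=True):
    """Direct numeric matrix: first feature shifted by `effect` in class 1."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, 0] += effect
    ids = [f"s{i:03d}" for i in range(n)]
    values = pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(n_features)])
    meta = None
    if metadata:
        meta = pd.DataFrame(
            {
                "sex": rng.choice(["M", "F"], size=n),
                "age": rng.integers(40, 85, size=n),
                "stage": [""] * n_per_class
                + list(rng.choice(["I", "II", "III", "IV"], size=n_per_class)),
            },
            index=ids,
        )
    return pf.FeatureMatrix(values, pd.Series(y, index=ids), meta)


class TestRocMetrics:
    def test_known_auc(self):
        out = pf.roc_metrics([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0])
        assert out["auc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert pf.roc_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])["auc"] == 1.0

    def test_all_tied_scores_half(self):
        assert pf.roc_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pf.roc_metrics([0.1, 0.2], [1, 1])

    def test_matches_concordant_pair_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # ties likely
            expected = oracles.auc_concordant_pairs(scores, labels)
            assert pf.roc_metrics(scores, labels)["auc"] == pytest.approx(expected)


class TestOperatingPoint:
    def test_separable_case(self):
        op = pf.operating_point([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 0.95)
        assert 0.3 < op["threshold"] <= 0.8
        assert op["sensitivity"] == 1.0
        assert op["specificity"] == 1.0

    def test_specificity_always_meets_target(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.random(60)
            labels = rng.integers(0, 2, size=60)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            for target in (0.90, 0.95, 0.99):
                op = pf.operating_point(scores, labels, target)
                assert op["specificity"] >= target

    def test_null_scores_sensitivity_tracks_complement(self):
        rng = np.random.default_rng(5)
        n = 4000
        scores = rng.random(n)
        labels = np.repeat([0, 1], n // 2)
        op = pf.operating_point(scores, labels, 0.90)
        se = np.sqrt(0.1 * 0.9 / (n // 2))
        assert op["sensitivity"] == pytest.approx(0.10, abs=3 * se + 2 / (n // 2))

    def test_tied_scores_deterministic(self):
        scores = [0.2, 0.5, 0.5, 0.5, 0.9]
        labels = [0, 0, 1, 1, 1]
        op1 = pf.operating_point(scores, labels, 0.95)
        op2 = pf.operating_point(list(reversed(scores)), list(reversed(labels)), 0.95)
        assert op1["threshold"] == op2["threshold"]
        assert op1["confusion"] == op2["confusion"]
        # threshold must exclude the tied benign score (>= rule)
        assert op1["specificity"] == 1.0

    def test_confusion_counts_sum_to_n(self):
        op = pf.operating_point([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 0.9)
        assert sum(op["confusion"].values()) == 4


class TestTrainGLM:
    def test_strong_signal_high_auc(self):
        m = _toy_matrix(n_per_class=20, effect=3.0, seed=1)
        res = pf.train_glm_cv(m, folds=5, repeats=2, seed=2)
        auc = pf.roc_metrics(
            res.oof_scores.to_numpy(), m.labels.loc[res.oof_scores.index].to_numpy()
        )["auc"]
        assert auc >= 0.95
        assert res.oof_scores.between(0, 1).all()

    def test_single_class_rejected(self):
        m = _toy_matrix(n_per_class=12, seed=3)
        single = m.subset([s for s in m.sample_ids if m.labels[s] == 0])
        with pytest.raises(ValueError):
            pf.train_glm_cv(single, folds=5, repeats=1, seed=1)

    def test_order_invariance(self):
        m = _toy_matrix(n_per_class=10, effect=2.0, seed=4)
        res1 = pf.train_glm_cv(m, folds=5, repeats=2, seed=7)
        shuffled_ids = list(reversed(m.sample_ids))
        shuffled_cols = list(reversed(m.feature_names))
        m2 = pf.FeatureMatrix(
            m.values.loc[shuffled_ids, shuffled_cols],
            m.labels.loc[shuffled_ids],
            m.metadata.loc[shuffled_ids],
        )
        res2 = pf.train_glm_cv(m2, folds=5, repeats=2, seed=7)
        pd.testing.assert_series_equal(res1.oof_scores, res2.oof_scores)

    def test_repeat_count_stability(self):
        m = _toy_matrix(n_per_class=15, effect=2.0, seed=5)
        auc = {}
        for repeats in (1, 5):
            res = pf.train_glm_cv(m, folds=5, repeats=repeats, seed=9)
            auc[repeats] = pf.roc_metrics(
                res.oof_scores.to_numpy(), m.labels.loc[res.oof_scores.index].to_numpy()
            )["auc"]
        assert abs(auc[1] - auc[5]) <= 0.03

    def test_missing_values_imputed_split_confined(self):
        m = _toy_matrix(n_per_class=10, effect=2.5, seed=6)
        m.values.iloc[0, 3] = np.nan
        res = pf.train_glm_cv(m, folds=5, repeats=1, seed=1)
        assert np.isfinite(res.oof_scores).all()


class TestPredictScores:
    def test_locked_model_round_trip(self, tmp_path):
        m = _toy_matrix(n_per_class=12, effect=2.0, seed=8)
        res = pf.train_glm_cv(m, folds=4, repeats=1, seed=3)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = pf.ModelResult.from_json(path)
        np.testing.assert_allclose(
            pf.predict_scores(back, m).to_numpy(), pf.predict_scores(res, m).to_numpy()
        )

    def test_all_zero_standardised_features_give_intercept(self):
        m = _toy_matrix(n_per_class=12, effect=1.5, seed=9)
        res = pf.train_glm_cv(m, folds=4, repeats=1, seed=4)
        mean_row = pd.DataFrame(
            [res.model.scale_mean], columns=res.model.feature_names, index=["avg"]
        )
        score = res.model.predict(mean_row)[0]
        expected = 1.0 / (1.0 + np.exp(-res.model.intercept))
        assert score == pytest.approx(expected)

    def test_duplicated_row_identical_scores(self):
        m = _toy_matrix(n_per_class=12, effect=1.5, seed=10)
        res = pf.train_glm_cv(m, folds=4, repeats=1, seed=5)
        dup = pf.FeatureMatrix(
            pd.concat([m.values.iloc[[0]].rename(index={m.sample_ids[0]: "a"}),
                       m.values.iloc[[0]].rename(index={m.sample_ids[0]: "b"})])
        )
        scores = pf.predict_scores(res, dup)
        assert scores["a"] == scores["b"]

    def test_missing_column_named_in_error(self):
        m = _toy_matrix(n_per_class=12, seed=11)
        res = pf.train_glm_cv(m, folds=4, repeats=1, seed=6)
        broken = pf.FeatureMatrix(m.values.drop(columns=["f3"]))
        with pytest.raises(ValueError, match="f3"):
            pf.predict_scores(res, broken)

    def test_score_monotone_in_positive_feature(self):
        m = _toy_matrix(n_per_class=15, effect=3.0, seed=12)
        res = pf.train_glm_cv(m, folds=5, repeats=1, seed=7)
        coef = dict(zip(res.model.feature_names, res.model.coef))
        assert coef["f0"] > 0  # the injected signal feature
        row = m.values.iloc[[0]].copy()
        base = res.model.predict(row)[0]
        row["f0"] += 1.0
        assert res.model.predict(row)[0] > base


class TestSubgroups:
    def test_shuffled_sex_close_to_overall(self):
        m = _toy_matrix(n_per_class=40, effect=2.0, seed=13)
        res = pf.train_glm_cv(m, folds=5, repeats=2, seed=8)
        scores = res.oof_scores.to_numpy()
        labels = m.labels.loc[res.oof_scores.index].to_numpy()
        meta = m.metadata.loc[res.oof_scores.index]
        overall = pf.roc_metrics(scores, labels)["auc"]
        groups = pf.subgroup_eval(scores, labels, meta)
        for key in ("sex_female", "sex_male"):
            assert abs(groups[key]["auc"] - overall) <= 0.1

    def test_empty_subgroup_absent(self):
        m = _toy_matrix(n_per_class=10, effect=2.0, seed=14)
        meta = m.metadata.copy()
        meta["sex"] = "M"
        groups = pf.subgroup_eval(
            np.linspace(0, 1, 20), m.labels.to_numpy(), meta.loc[m.sample_ids]
        )
        assert "sex_female" not in groups
        assert "sex_male" in groups
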