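import numpy as np
import pandas as pd
import pytest

import cppmine as cm
from cppmine.descriptors import FeatureMatrix
from cppmine.ensemble import (
    CPPEnsemble,
    EnsembleConfig,
    apply_grid_result,
    evaluate,
    grid_search,
    split_train_validation,
)
from . import oracles


def dummy_matrix(n, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    y = pd.Series(rng.integers(0, 2, size=n), index=X.index)
    return FeatureMatrix(X, y)


@pytest.fixture(scope="module")
def small_fit(small_labeled_set):
    sel, _ = cm.select_features(cm.featurize(small_labeled_set), folds=5, seed=7)
    return CPPEnsemble(sel, EnsembleConfig(seed=7)).fit()


class TestSplit:
    def test_2380_rows_split_2023_357(self):
        train, val = split_train_validation(dummy_matrix(2380), EnsembleConfig(seed=40))
        assert (len(train), len(val)) == (2023, 357)

    def test_same_seed_identical(self):
        m = dummy_matrix(200, seed=1)
        t1, v1 = split_train_validation(m, EnsembleConfig(seed=40))
        t2, v2 = split_train_validation(m, EnsembleConfig(seed=40))
        assert t1.X.equals(t2.X) and v1.X.equals(v2.X)

    def test_partition_of_input(self):
        m = dummy_matrix(100, seed=2)
        train, val = split_train_validation(m, EnsembleConfig(seed=40))
        idx = sorted(list(train.X.index) + list(val.X.index))
        assert idx == sorted(m.X.index)
        assert set(train.X.index).isdisjoint(val.X.index)

    def test_requires_labels(self):
        m = dummy_matrix(50)
        m.y = None
        with pytest.raises(ValueError):
            split_train_validation(m, EnsembleConfig())


class TestEvaluate:
    def test_confusion_arithmetic(self):
        truth = [1] * 90 + [0] * 10 + [1] * 10 + [0] * 90
        pred = [1] * 100 + [0] * 100
        proba = [0.9] * 100 + [0.1] * 100
        m = evaluate(truth, proba, pred)
        assert (m.tp, m.fp, m.fn, m.tn) == (90, 10, 10, 90)
        assert m.precision == m.recall == m.f1 == m.accuracy == 0.9

    def test_perfect_ranking_auc_one(self):
        m = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m.roc_auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(12)
        truth = rng.integers(0, 2, size=2000)
        proba = rng.random(2000)
        assert evaluate(truth, proba).roc_auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_truth_auc_absent(self, caplog):
        with caplog.at_level("WARNING"):
            m = evaluate([1, 1, 1], [0.2, 0.6, 0.9])
        assert m.roc_auc is None

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            truth = rng.integers(0, 2, size=n)
            if len(np.unique(truth)) < 2:
                continue
            proba = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
            got = evaluate(truth, proba)
            exp = oracles.confusion_metrics(truth, (proba >= 0.5).astype(int))
            for k, v in exp.items():
                assert getattr(got, k) == pytest.approx(v)
            assert got.roc_auc == pytest.approx(oracles.roc_auc_pairs(truth, proba))


class TestGridSearch:
    def test_one_point_grid_returned(self, small_labeled_set):
        sel, _ = cm.select_features(cm.featurize(small_labeled_set), folds=5, seed=7)
        cfg = EnsembleConfig(seed=7, cv_folds=5)
        train, _ = split_train_validation(sel, cfg)
        best = grid_search(train, {"knn": {"n_neighbors": [18]}}, cfg)
        assert best == {"knn": {"n_neighbors": 18}}

    def test_degraded_variants_lose_to_optimum(self, small_labeled_set):
        sel, _ = cm.select_features(cm.featurize(small_labeled_set), folds=5, seed=7)
        cfg = EnsembleConfig(seed=7, cv_folds=5)
        train, _ = split_train_validation(sel, cfg)
        best = grid_search(
            train,
            {"knn": {"n_neighbors": [18, 1]}, "rf": {"n_estimators": [20, 1]}},
            cfg,
        )
        assert best["knn"]["n_neighbors"] == 18
        assert best["rf"]["n_estimators"] == 20

    def test_fold_count_exceeding_class_size_errors(self):
        m = dummy_matrix(12)
        with pytest.raises(ValueError, match="cv_folds"):
            grid_search(m, {"knn": {"n_neighbors": [3]}}, EnsembleConfig(cv_folds=10))

    def test_apply_grid_result_roundtrip(self):
        cfg = EnsembleConfig()
        out = apply_grid_result(cfg, {"gbt": {"max_depth": 4, "learning_rate": 0.2}})
        assert out.boosting.max_depth == 4 and out.boosting.learning_rate == pytest.approx(0.2)
        assert cfg.boosting.max_depth == 8  # original untouched


class TestTrainedEnsemble:
    def test_probabilities_and_classes_valid(self, small_fit):
        proba, pred = small_fit.predict(small_fit.validation)
        assert np.all((proba >= 0) & (proba <= 1))
        assert set(pred) <= {0, 1}

    def test_seeded_refit_identical_predictions(self, small_labeled_set):
        sel, _ = cm.select_features(cm.featurize(small_labeled_set), folds=5, seed=7)
        r1 = CPPEnsemble(sel, EnsembleConfig(seed=7)).fit()
        r2 = CPPEnsemble(sel, EnsembleConfig(seed=7)).fit()
        p1, _ = r1.predict(r1.validation)
        p2, _ = r2.predict(r1.validation)
        assert np.array_equal(p1, p2)

    def test_manifest_mismatch_is_explicit_error(self, small_fit):
        bad = small_fit.validation.X.rename(columns={small_fit.feature_manifest[0]: "bogus"})
        with pytest.raises(ValueError, match="bogus"):
            small_fit.predict(bad)

    def test_duplicated_row_identical_outputs(self, small_fit):
        row = small_fit.validation.X.iloc[[0]]
        both = pd.concat([row, row])
        proba, pred = small_fit.predict(both)
        assert proba[0] == proba[1] and pred[0] == pred[1]

    def test_class_one_scores_above_class_zero_on_heldout(self, small_fit):
        proba, _ = small_fit.predict(small_fit.validation)
        y = np.asarray(small_fit.validation.y, dtype=int)
        assert proba[y == 1].mean() > proba[y == 0].mean()

    def test_single_class_input_rejected(self):
        m = dummy_matrix(40)
        m.y = pd.Series(np.ones(40, dtype=int), index=m.X.index)
        with pytest.raises(ValueError):
            CPPEnsemble(m)

    def test_summary_mentions_metrics_and_config(self, small_fit):
        text = small_fit.summary()
        assert "precision" in text and "k=18" in text and "validation" in text

    def test_save_writes_model_and_sidecar(self, small_fit, tmp_path):
        small_fit.save(tmp_path / "m.pkl", tmp_path / "m.json")
        import json

        sidecar = json.loads((tmp_path / "m.json").read_text())
        assert sidecar["feature_manifest"] == small_fit.feature_manifest
        assert sidecar["seed"] == 7

    def test_stacking_not_worse_than_best_base_learner(self, benchmark_results):
        # checked at benchmark scale; tiny validation splits are too noisy
        y = np.asarray(benchmark_results.validation.y, dtype=int)
        base_prec = [
            evaluate(y, p).precision
            for p in benchmark_results.predict_base_learners(benchmark_results.validation).values()
        ]
        assert benchmark_results.validation_metrics.precision >= max(base_prec) - 0.02


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"train_fraction": 0.0},
        {"train_fraction": 1.0},
    ])
    def test_bad_fractions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnsembleConfig(**kwargs)

    def test_bad_learning_rate_rejected(self):
        from cppmine.ensemble import BoostingConfig

        with pytest.raises(ValueError):
            EnsembleConfig(boosting=BoostingConfig(learning_rate=0.0))
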