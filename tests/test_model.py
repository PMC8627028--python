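import numpy as np
import pandas as pd
import pytest

from asmqual.metrics import MODEL_FEATURES
from asmqual.model import (
    AssemblyQualityModel,
    EvalResult,
    QualityModelResults,
    SplitSpec,
    evaluate,
    finalize_and_predict,
    select_best,
    split_data,
    train_model,
)


def _linear_table(n=60, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(
        rng.uniform(0, 100, size=(n, len(MODEL_FEATURES))), columns=MODEL_FEATURES
    )
    t["score"] = (
        0.5 * t["normN50"] - 0.3 * t["gap_perc"] + 0.8 * t["error_free_bases"]
        + rng.normal(0, noise, n)
    )
    return t


class TestSplitData:
    def test_416_gives_333_83(self):
        t = _linear_table(n=416)
        tr, te = split_data(t, SplitSpec(seed=1))
        assert (len(tr), len(te)) == (333, 83)

    def test_10_gives_8_2(self):
        tr, te = split_data(_linear_table(n=10), SplitSpec(seed=1))
        assert (len(tr), len(te)) == (8, 2)

    def test_same_seed_identical(self):
        t = _linear_table(n=50)
        a = split_data(t, SplitSpec(seed=7))
        b = split_data(t, SplitSpec(seed=7))
        assert a[0].index.equals(b[0].index) and a[1].index.equals(b[1].index)

    def test_partition_property(self):
        t = _linear_table(n=37)
        tr, te = split_data(t, SplitSpec(seed=3))
        assert sorted([*tr.index, *te.index]) == list(range(37))

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.2)


class _Stub:
    def __init__(self, pred):
        self.pred = np.asarray(pred, float)

    def predict(self, X):
        return self.pred[: len(X)]


def _stub_results(pred, target="score"):
    shell = AssemblyQualityModel.__new__(AssemblyQualityModel)
    shell.features = list(MODEL_FEATURES)
    shell.target = target
    shell.family = "glm"
    shell.table = pd.DataFrame()
    return QualityModelResults(
        model=shell, estimator=_Stub(pred), hyperparameters={},
        cv_rmse=0.0, seed=0, data_digest="x",
    )


class TestEvaluate:
    def test_matches_explicit_formulas(self):
        rng = np.random.default_rng(0)
        t = _linear_table(n=40)
        pred = rng.uniform(0, 100, 40)
        res = _stub_results(pred)
        ev = res.evaluate(t)
        y = t["score"].to_numpy()
        assert ev.rmse == pytest.approx(np.sqrt(np.mean((pred - y) ** 2)), abs=1e-9)
        assert ev.r_squared == pytest.approx(np.corrcoef(pred, y)[0, 1] ** 2, abs=1e-9)
        ssr = ((y - pred) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert ev.r_squared_resid == pytest.approx(1 - ssr / sst, abs=1e-9)

    def test_perfect_predictions(self):
        t = _linear_table(n=30)
        ev = _stub_results(t["score"].to_numpy()).evaluate(t)
        assert ev.rmse == 0.0 and ev.r_squared == pytest.approx(1.0)

    def test_constant_predictions_warn_zero_r2(self):
        t = _linear_table(n=30)
        with pytest.warns(UserWarning):
            ev = _stub_results(np.full(30, t["score"].mean())).evaluate(t)
        assert ev.r_squared == 0.0

    def test_empty_test_errors(self):
        with pytest.raises(ValueError):
            _stub_results([1.0]).evaluate(_linear_table(n=5).iloc[:0])


class TestTraining:
    def test_glm_recovers_noiseless_linear(self):
        t = _linear_table(n=60, noise=0.0)
        res = train_model(t, "glm", seed=0)
        assert res.cv_rmse == pytest.approx(0.0, abs=1e-6)
        ev = res.evaluate(t)
        assert ev.rmse == pytest.approx(0.0, abs=1e-6)

    def test_rf_beats_glm_on_nonlinear_target(self, synthetic_table):
        tr, te = split_data(synthetic_table, SplitSpec(seed=0))
        feats = list(MODEL_FEATURES)
        rf = train_model(tr, "rf", seed=0, features=feats, n_trees=150)
        glm = train_model(tr, "glm", seed=0, features=feats)
        assert rf.evaluate(te).rmse < glm.evaluate(te).rmse

    def test_constant_target_predicts_constant(self):
        t = _linear_table(n=60)
        t["score"] = 42.0
        with pytest.warns(UserWarning):
            res = train_model(t, "rf", seed=0, n_trees=50)
        m = dict.fromkeys(MODEL_FEATURES, 10.0)
        assert res.predict(m) == pytest.approx(42.0)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            train_model(_linear_table(), "boosted")

    def test_too_few_rows_for_cv(self):
        with pytest.raises(ValueError, match="rows"):
            train_model(_linear_table(n=12), "rf")

    def test_feature_column_order_invariance(self, synthetic_table):
        feats = list(MODEL_FEATURES)
        res = train_model(synthetic_table, "rf", seed=0, features=feats, n_trees=50)
        rev = synthetic_table[list(synthetic_table.columns[::-1])]
        p1 = res.predict(synthetic_table.head(20))
        p2 = res.predict(rev.head(20))
        assert np.array_equal(p1, p2)

    def test_missing_feature_named(self, synthetic_table):
        res = train_model(synthetic_table, "glm", seed=0)
        with pytest.raises(ValueError, match="normN50"):
            res.predict({"gap_perc": 1.0})

    def test_summary_mentions_family_and_features(self, synthetic_table):
        res = train_model(synthetic_table, "glm", seed=0)
        s = res.summary()
        assert "glm" in s and "normN50" in s


class TestPersistence:
    def test_roundtrip_identical_predictions(self, synthetic_table, tmp_path):
        res = train_model(synthetic_table, "rf", seed=1, n_trees=100)
        res.save(tmp_path / "model")
        back = QualityModelResults.load(tmp_path / "model")
        rng = np.random.default_rng(5)
        probe = pd.DataFrame(
            rng.uniform(0, 100, size=(100, len(MODEL_FEATURES))),
            columns=MODEL_FEATURES,
        )
        assert np.array_equal(res.predict(probe), back.predict(probe))
        assert back.family == "rf" and back.feature_names == res.feature_names


class TestSelection:
    def test_lowest_rmse_wins(self):
        results = {
            "glm": EvalResult(16.413, 0.775, 0.7),
            "elastic_net": EvalResult(16.520, 0.773, 0.7),
            "knn": EvalResult(13.615, 0.840, 0.8),
            "rf": EvalResult(12.697, 0.860, 0.85),
            "svm_linear": EvalResult(17.190, 0.774, 0.7),
            "svm_poly": EvalResult(14.363, 0.843, 0.8),
        }
        assert select_best(results) == "rf"

    def test_single_entry(self):
        assert select_best({"knn": EvalResult(5.0, 0.5, 0.5)}) == "knn"

    def test_tie_broken_by_r_squared(self):
        results = {
            "glm": EvalResult(10.0, 0.7, 0.7),
            "knn": EvalResult(10.0, 0.9, 0.9),
        }
        assert select_best(results) == "knn"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best({})


class TestFinalize:
    def test_perfect_metrics_score_near_training_ceiling(self):
        # degradation-style table containing perfect instances at score 100
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(80):
            q = rng.uniform(0, 1)
            rows.append(
                {
                    "normN50": 100 * (1 - 0.9 * q), "gap_perc": 30 * q,
                    "clip": 20 * q, "error_free_bases": 100 * (1 - q),
                    "low_fc_over_gap": 40 * q, "low_fc_in_contig": 50 * q,
                    "score": 100 * (1 - q),
                }
            )
            rows.append(
                {
                    "normN50": 100.0, "gap_perc": 0.0, "clip": 0.0,
                    "error_free_bases": 100.0, "low_fc_over_gap": 0.0,
                    "low_fc_in_contig": 0.0, "score": 100.0,
                }
            )
        t = pd.DataFrame(rows)
        perfect = {
            "normN50": 100.0, "gap_perc": 0.0, "clip": 0.0,
            "error_free_bases": 100.0, "low_fc_over_gap": 0.0,
            "low_fc_in_contig": 0.0,
        }
        score = finalize_and_predict("rf", t, perfect, seed=0, n_trees=100)
        assert score == pytest.approx(100.0, abs=2.0)

    def test_degradation_series_scores_non_increasing(self, small_training_table):
        res = train_model(small_training_table, "rf", seed=0, n_trees=150)
        for _, g in small_training_table.groupby("organism"):
            g = g.sort_values("snp_rate")
            pred = res.predict(g)
            assert np.all(np.diff(pred) <= 1.0)  # non-increasing up to noise
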