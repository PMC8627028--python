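import numpy as np
import pandas as pd
import pytest

from asmqual.features import (
    _discretize,
    _mi,
    correlation_matrix,
    exhaustive_subset_search,
    jmim_rank,
    pearson_filter,
    permutation_importance,
    run_cascade,
)
from asmqual.metrics import METRIC_NAMES
from asmqual.model import train_model
from helpers import brute_jmim_order, discrete_mi


def _table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(rng.normal(size=(n, 13)), columns=METRIC_NAMES)
    t["score"] = t["normN50"] * 2 + rng.normal(0, 0.1, n)
    return t


class TestPearsonFilter:
    def test_feature_equal_to_target_retained(self):
        t = _table()
        t["gap_perc"] = t["score"]
        keep, rs = pearson_filter(t)
        assert "gap_perc" in keep
        assert rs["gap_perc"] == pytest.approx(1.0)

    def test_iid_noise_removed(self):
        rng = np.random.default_rng(1)
        t = _table(n=10_000, seed=1)
        t["coll_repeat"] = rng.normal(size=10_000)  # independent of score
        keep, rs = pearson_filter(t)
        assert abs(rs["coll_repeat"]) < 0.1
        assert "coll_repeat" not in keep

    def test_zero_variance_removed_with_warning(self):
        t = _table()
        t["links"] = 1.0
        with pytest.warns(UserWarning, match="links"):
            keep, rs = pearson_filter(t)
        assert "links" not in keep and np.isnan(rs["links"])

    def test_row_order_and_affine_invariance(self):
        t = _table(seed=3)
        keep1, rs1 = pearson_filter(t)
        shuffled = t.sample(frac=1, random_state=5)
        t2 = t.copy()
        t2["clip"] = t2["clip"] * 7.5 - 3.0
        keep2, _ = pearson_filter(shuffled)
        keep3, rs3 = pearson_filter(t2)
        assert keep1 == keep2 == keep3
        assert rs1["clip"] == pytest.approx(rs3["clip"])

    def test_constant_target_errors(self):
        t = _table()
        t["score"] = 1.0
        with pytest.raises(ValueError):
            pearson_filter(t)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self):
        mat, _ = correlation_matrix(_table())
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_duplicate_column_flagged(self):
        t = _table()
        t["clip"] = t["links"]
        mat, flagged = correlation_matrix(t)
        assert mat.loc["clip", "links"] == pytest.approx(1.0)
        assert any({a, b} == {"clip", "links"} for a, b, _ in flagged)

    def test_independent_features_near_zero(self):
        t = _table(n=10_000, seed=7)
        mat, _ = correlation_matrix(t, features=["clip", "links", "gap_perc"])
        off = mat.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05


class TestJmim:
    def test_xor_truth_table(self):
        rows = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        t = pd.DataFrame(rows, columns=["x1", "x2", "x3"])
        t["score"] = t["x1"] ^ t["x2"]
        order = jmim_rank(t, ["x1", "x2", "x3"], k=3, bins=2)
        assert set(order[:2]) == {"x1", "x2"}
        assert order[2] == "x3"

    def test_duplicate_feature_ranked_last(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"a": rng.normal(size=300)})
        t["dup"] = t["a"]
        t["b"] = rng.normal(size=300)
        t["score"] = t["a"] + 0.5 * t["b"]
        order = jmim_rank(t, ["a", "dup", "b"], k=3)
        assert order[-1] == "dup"

    def test_matches_bruteforce_on_small_discrete_tables(self):
        rng = np.random.default_rng(4)
        for trial in range(15):
            n = int(rng.integers(8, 17))
            k = int(rng.integers(2, 5))
            t = pd.DataFrame(
                rng.integers(0, 3, size=(n, k)),
                columns=[f"f{i}" for i in range(k)],
            )
            t["score"] = rng.integers(0, 3, size=n)
            order = jmim_rank(t, list(t.columns[:-1]), k=k, bins=3)
            cols = {f: _discretize(t[f].to_numpy(float), 3) for f in t.columns[:-1]}
            y = _discretize(t["score"].to_numpy(float), 3)
            assert order == brute_jmim_order(cols, y)

    def test_mi_estimator_matches_enumeration(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 50)
        z = rng.integers(0, 2, 50)
        y = (x + z) % 3
        assert _mi(x, y) == pytest.approx(discrete_mi(x, y))
        assert _mi(x, z, y) == pytest.approx(discrete_mi(x, z, y))

    def test_k_too_large_errors(self):
        t = _table()
        with pytest.raises(ValueError):
            jmim_rank(t, ["clip", "links"], k=3)


class TestPermutationImportance:
    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(
            {
                "sig": rng.normal(size=300),
                "n1": rng.normal(size=300),
                "n2": rng.normal(size=300),
            }
        )
        t["score"] = t["sig"] * 3
        res = train_model(t, "rf", seed=0, features=["sig", "n1", "n2"], n_trees=100)
        inc = permutation_importance(res, t, reps=2, seed=0)
        assert max(inc, key=inc.get) == "sig"
        assert inc["sig"] > 50
        assert abs(inc["n1"]) < 20 and abs(inc["n2"]) < 20

    def test_zero_reps_errors(self):
        with pytest.raises(ValueError):
            permutation_importance(None, _table(), reps=0)

    def test_non_forest_rejected(self):
        t = _table()
        res = train_model(t, "glm", seed=0, features=["clip"], n_trees=10)
        with pytest.raises(ValueError):
            permutation_importance(res, t, reps=1)


class TestSubsetSearch:
    def test_exact_single_candidate(self):
        t = _table()
        t["clip"] = t["score"]
        best, final, _ = exhaustive_subset_search(t, ["clip"], max_size=1)
        assert best[1][1] == pytest.approx(1.0)
        assert final == ["clip"]

    def test_noise_candidates_low_r2(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame(rng.normal(size=(1000, 3)), columns=["a", "b", "c"])
        t["score"] = rng.normal(size=1000)
        best, _, _ = exhaustive_subset_search(t, ["a", "b", "c"], max_size=3)
        assert all(r2 < 0.02 for _, r2, _ in best.values())

    def test_r2_nondecreasing_in_size(self, synthetic_table):
        best, _, _ = exhaustive_subset_search(
            synthetic_table,
            ["normN50", "gap_perc", "clip", "error_free_bases", "low_fc_in_contig"],
            max_size=5,
        )
        r2s = [best[s][1] for s in sorted(best)]
        assert all(a <= b + 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_sign_contradiction_excluded(self):
        # x2 is a noisy copy of x1; in the joint OLS its weight flips sign
        rng = np.random.default_rng(9)
        x1 = rng.normal(size=400)
        x2 = x1 + rng.normal(0, 0.05, 400)
        t = pd.DataFrame({"x1": x1, "x2": x2})
        t["score"] = 2 * x1 - 1 * x2 + rng.normal(0, 0.01, 400)
        best, final, excluded = exhaustive_subset_search(t, ["x1", "x2"], max_size=2)
        # both features correlate positively with the target, but the best
        # 2-subset gives x2 a negative weight -> it cannot be in the final set
        assert final == ["x1"]
        assert excluded == ["x2"]

    def test_too_many_candidates_refused(self):
        t = _table()
        with pytest.raises(ValueError):
            exhaustive_subset_search(t, [f"c{i}" for i in range(21)])


class TestCascade:
    def test_full_cascade_structure(self, synthetic_table):
        rep = run_cascade(synthetic_table, seed=0, n_trees=100)
        assert set(rep.final_features) <= set(rep.retained)
        assert len(rep.final_features) <= 6
        assert set(rep.jmim_ranking) == set(rep.retained)
        # report serialises
        assert "pearson_r" in rep.to_json()
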