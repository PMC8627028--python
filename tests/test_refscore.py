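import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asmqual.refscore import (
    IDEAL_VECTOR,
    WORST_DISTANCE,
    DiffSummary,
    _anchored_matches,
    _llcs_bitparallel,
    count_differences,
    external_scale,
    ideal_distance,
    internal_scale,
    percent_matching_bases,
    score_instances,
)
from asmqual.simulate import ErrorProfile, mutate_assembly, random_assembly
from helpers import lcs_quadratic, oracle_diffs

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestCountDifferences:
    def test_identical_sequences(self):
        s = random_assembly(1, 1000, seed=1).sequences[0][1]
        assert count_differences(s, s).total_differences == 0

    def test_single_substitution(self):
        s = random_assembly(1, 1000, seed=2).sequences[0][1]
        q = s[:500] + ("A" if s[500] != "A" else "C") + s[501:]
        assert count_differences(q, s).total_differences == 1

    def test_deleted_block(self):
        s = random_assembly(1, 1000, seed=3).sequences[0][1]
        q = s[:400] + s[450:]
        assert count_differences(q, s).total_differences == 50

    def test_matches_quadratic_oracle_on_mutated_pairs(self):
        rng = np.random.default_rng(7)
        for t in range(30):
            L = int(rng.integers(200, 1500))
            ref = random_assembly(1, L, seed=300 + t)
            rate = float(rng.uniform(0, 0.10))
            mut, _ = mutate_assembly(
                ref, ErrorProfile(snp_rate=rate, indel_rate=rate / 10), seed=400 + t
            )
            q, r = mut.sequences[0][1], ref.sequences[0][1]
            assert count_differences(q, r).total_differences == oracle_diffs(r, q)

    def test_anchored_path_agrees_with_exact(self):
        ref = random_assembly(1, 12_000, seed=5)
        mut, _ = mutate_assembly(
            ref, ErrorProfile(snp_rate=0.03, indel_rate=0.003), seed=6
        )
        r, q = ref.sequences[0][1], mut.sequences[0][1]
        assert _anchored_matches(r, q, 21) == _llcs_bitparallel(r, q)

    def test_no_anchors_fully_diverged(self):
        # disjoint alphabet usage is impossible for DNA; use the large-input
        # anchored path with an unrelated query instead
        with pytest.warns(UserWarning, match="no alignment anchors"):
            m = _anchored_matches("ACGT" * 30, "TTTT" * 30, 21)
        assert m == 0

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            count_differences("ACGT", "")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_bitparallel_lcs_equals_quadratic_dp(self, a, b):
        assert _llcs_bitparallel(a, b) == lcs_quadratic(a, b)


class TestPercentMatchingBases:
    @pytest.mark.parametrize(
        "ref_len,diffs,expected",
        [(1000, 0, 100.0), (1000, 25, 97.5), (1000, 1000, 0.0)],
    )
    def test_formula(self, ref_len, diffs, expected):
        assert percent_matching_bases(DiffSummary(ref_len, diffs)) == expected

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            percent_matching_bases(DiffSummary(0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_self_alignment_is_always_100(self, s):
        assert percent_matching_bases(count_differences(s, s)) == 100.0

    def test_strictly_decreasing_in_differences(self):
        vals = [
            percent_matching_bases(DiffSummary(1000, d)) for d in range(0, 1000, 50)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _ideal_row(**overrides):
    row = dict(IDEAL_VECTOR)
    row.update(overrides)
    return row


class TestIdealDistance:
    def test_identity_is_zero(self):
        assert ideal_distance(_ideal_row()) == 0.0

    def test_single_coordinate(self):
        assert ideal_distance(_ideal_row(gap_perc=3.0)) == 3.0

    def test_three_four_five(self):
        assert ideal_distance(_ideal_row(gap_perc=3.0, normN50=96.0)) == 5.0

    def test_missing_metric_named(self):
        row = _ideal_row()
        del row["clip"]
        with pytest.raises(KeyError, match="clip"):
            ideal_distance(row)


class TestScaling:
    def test_single_instance_keeps_pmb(self):
        df = pd.DataFrame({"pmb": [97.0], "distance": [5.0]})
        out = internal_scale(df)
        assert out["scaled_score"].iloc[0] == 97.0

    def test_equal_distances_keep_pmb(self):
        df = pd.DataFrame({"pmb": [90.0, 80.0], "distance": [4.0, 4.0]})
        out = internal_scale(df)
        assert list(out["scaled_score"]) == [90.0, 80.0]

    def test_internal_hand_example(self):
        df = pd.DataFrame({"pmb": [98.0, 100.0], "distance": [2.0, 12.0]})
        out = internal_scale(df, worst_distance=200.0)
        assert out["scaled_score"].iloc[0] == 98.0
        assert out["scaled_score"].iloc[1] == pytest.approx(95.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            internal_scale(pd.DataFrame({"pmb": [], "distance": []}))

    def test_external_single_organism_identity(self):
        df = pd.DataFrame(
            {"organism": ["a", "a"], "distance": [1.0, 5.0],
             "scaled_score": [100.0, 90.0]}
        )
        out = external_scale(df)
        assert list(out["final_score"]) == list(df["scaled_score"])

    def test_external_hand_example(self):
        df = pd.DataFrame(
            {
                "organism": ["a", "b", "b"],
                "distance": [3.0, 23.0, 50.0],
                "scaled_score": [100.0, 95.0, 80.0],
            }
        )
        out = external_scale(df, worst_distance=200.0)
        assert out["final_score"].iloc[0] == 100.0
        assert out["final_score"].iloc[1] == pytest.approx(95.0 * 0.9)
        assert out["final_score"].iloc[2] == pytest.approx(80.0 * 0.9)

    def test_order_preserved_when_pmb_and_distance_agree(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            d = np.sort(rng.uniform(0, 300, 6))
            pmb = np.sort(rng.uniform(0, 100, 6))[::-1]
            out = internal_scale(pd.DataFrame({"pmb": pmb, "distance": d}))
            s = out["scaled_score"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)

    def test_best_instance_fixed_point_through_both_rounds(self):
        df = pd.DataFrame(
            {
                "organism": ["a"] * 3 + ["b"] * 2,
                "pmb": [100.0, 95.0, 80.0, 99.0, 70.0],
                "distance": [1.0, 50.0, 120.0, 30.0, 200.0],
            }
        )
        out = score_instances(df)
        best = out.loc[out["distance"].idxmin()]
        assert best["final_score"] == best["pmb"]

    def test_final_score_monotone_in_degradation(self):
        # a degradation series: pmb falls while distance grows
        df = pd.DataFrame(
            {
                "organism": ["x"] * 5,
                "pmb": [100.0, 94.0, 86.0, 82.0, 78.0],
                "distance": [2.0, 50.0, 120.0, 200.0, 260.0],
            }
        )
        out = score_instances(df)
        s = out["final_score"].to_numpy()
        assert np.all(np.diff(s) < 0)
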