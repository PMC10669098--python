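import numpy as np
import pandas as pd
import pytest

from subtme.cci import (
    count_interactions,
    interaction_score,
    permutation_test,
    specificity_filter,
    subsample_cells,
)
from subtme.exceptions import ValidationError
from subtme.io import LRPair

from conftest import make_em, simple_annotation


def _matrix_with_means(gene_means: dict, n_per_group: int, groups):
    """Deterministic matrix: each gene has a constant value per group."""
    genes = sorted(gene_means)
    cols = []
    labels = []
    for g_i, grp in enumerate(groups):
        for _ in range(n_per_group):
            cols.append([gene_means[g][g_i] for g in genes])
            labels.append(grp)
    X = np.array(cols, dtype=float).T
    m = make_em(X, genes=genes)
    m.normalized = m.counts.astype(float)
    ann = simple_annotation(list(m.obs), labels)
    return m, ann


class TestInteractionScore:
    def test_mean_of_means_arithmetic(self):
        m, ann = _matrix_with_means({"L": (2.0, 0.0), "R": (0.0, 4.0)}, 12, ["A", "B"])
        pair = LRPair("P", ("L",), ("R",))
        assert interaction_score(m, ann, pair, "A", "B") == pytest.approx(3.0)

    def test_expression_gate_zeroes_score(self):
        rng = np.random.default_rng(0)
        X = np.zeros((2, 40))
        X[0, :20] = 2.0  # ligand fine in A
        recv = np.zeros(20)
        recv[0] = 5.0  # receptor in 5% of B cells < 10% gate
        X[1, 20:] = recv
        m = make_em(X)
        m.normalized = m.counts.astype(float)
        ann = simple_annotation(list(m.obs), ["A"] * 20 + ["B"] * 20)
        pair = LRPair("P", ("G1",), ("G2",))
        assert interaction_score(m, ann, pair, "A", "B") == 0.0

    def test_multi_component_minimum_rule(self):
        m, ann = _matrix_with_means(
            {"L": (2.0, 2.0), "R1": (1.0, 1.0), "R2": (3.0, 3.0)}, 12, ["A", "B"]
        )
        pair = LRPair("P", ("L",), ("R1", "R2"))
        # receptor summary = min(1.0, 3.0) = 1.0 -> score (2 + 1) / 2
        assert interaction_score(m, ann, pair, "A", "B") == pytest.approx(1.5)

    def test_missing_gene_is_error(self):
        m, ann = _matrix_with_means({"L": (1.0, 1.0)}, 12, ["A", "B"])
        with pytest.raises(ValidationError):
            interaction_score(m, ann, LRPair("P", ("L",), ("NOPE",)), "A", "B")


class TestPermutationTest:
    def test_zero_observed_score_has_p_one(self):
        m, ann = _matrix_with_means({"L": (2.0, 0.0), "R": (0.0, 2.0)}, 15, ["A", "B"])
        res = permutation_test(m, ann, [LRPair("P", ("L",), ("R",))], n_perm=100, seed=0)
        zero = res[res["score"] == 0.0]
        assert (zero["p"] == 1.0).all()

    def test_deterministic_given_seed(self, default_cohort):
        _, m, ann = default_cohort
        pairs = [LRPair("P", ("BG-1",), ("BG-2",))]
        r1 = permutation_test(m, ann, pairs, n_perm=100, seed=3)
        r2 = permutation_test(m, ann, pairs, n_perm=100, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_n_perm_floor(self, default_cohort):
        _, m, ann = default_cohort
        with pytest.raises(ValidationError):
            permutation_test(m, ann, [LRPair("P", ("BG-1",), ("BG-2",))], n_perm=5)

    def test_p_at_least_add_one_floor(self, default_cohort):
        _, m, ann = default_cohort
        res = permutation_test(m, ann, [LRPair("P", ("BG-1",), ("BG-2",))], n_perm=100, seed=1)
        assert (res["p"] >= 1 / 101).all()


class TestCountInteractions:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["pair_id", "sender", "receiver", "score", "p"])

    def test_no_significant_pairs_gives_zero_matrix(self):
        scores = self._scores([("P1", "A", "B", 1.0, 0.5)])
        directed, total = count_interactions(scores)
        assert directed.to_numpy().sum() == 0

    def test_single_significant_pair(self):
        scores = self._scores([("P1", "A", "B", 1.0, 0.01)])
        directed, total = count_interactions(scores)
        assert directed.loc["A", "B"] == 1
        assert total.loc["A", "B"] == 1 and total.loc["B", "A"] == 1

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(21)
        rows = [
            (f"P{i}", rng.choice(["A", "B", "C"]), rng.choice(["A", "B", "C"]),
             1.0, float(rng.random()))
            for i in range(100)
        ]
        scores = self._scores(rows)
        directed, _ = count_interactions(scores, alpha=0.05)
        for s in "ABC":
            for r in "ABC":
                expected = sum(1 for _, ss, rr, _, p in rows if ss == s and rr == r and p < 0.05)
                assert directed.loc[s, r] == expected


class TestSubsample:
    def _ann(self):
        return simple_annotation(
            [f"c{i}" for i in range(160)], ["A"] * 150 + ["B"] * 10
        )

    def test_exact_size_and_small_groups_kept(self):
        out = subsample_cells(self._ann(), per_subtype=50, seed=0)
        sizes = out["subtype"].value_counts()
        assert sizes["A"] == 50 and sizes["B"] == 10

    def test_deterministic(self):
        a = subsample_cells(self._ann(), per_subtype=50, seed=9)
        b = subsample_cells(self._ann(), per_subtype=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_minimum_guard(self):
        with pytest.raises(ValidationError):
            subsample_cells(self._ann(), per_subtype=5)


class TestSpecificityFilter:
    def _scores(self, values):
        rows = []
        subtype_pairs = [("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")]
        for pair_id, vec in values.items():
            for (s, r), v in zip(subtype_pairs, vec):
                rows.append({"pair_id": pair_id, "sender": s, "receiver": r,
                             "score": v, "p": 0.01})
        return pd.DataFrame(rows)

    def test_constant_pair_has_cv_zero_and_ranks_last(self):
        scores = self._scores({"FLAT": [2, 2, 2, 2], "SPIKE": [4, 0, 0, 0]})
        out = specificity_filter(scores, top_n=10)
        assert out.iloc[-1]["pair_id"] == "FLAT"
        assert out.iloc[-1]["cv"] == 0.0

    def test_single_spike_closed_form(self):
        # score s in 1 of m=4 subtype pairs: cv = sqrt(m - 1) under population SD
        scores = self._scores({"SPIKE": [6, 0, 0, 0]})
        out = specificity_filter(scores, top_n=10)
        v = np.array([6.0, 0, 0, 0])
        oracle = v.std(ddof=0) / v.mean()
        assert out.iloc[0]["cv"] == pytest.approx(np.sqrt(3))
        assert out.iloc[0]["cv"] == pytest.approx(oracle)
        assert (out.iloc[0]["top_sender"], out.iloc[0]["top_receiver"]) == ("A", "A")

    def test_invariant_to_record_order(self):
        scores = self._scores({"P1": [1, 2, 3, 4], "P2": [5, 0, 1, 0]})
        out1 = specificity_filter(scores, top_n=10)
        out2 = specificity_filter(scores.sample(frac=1, random_state=4), top_n=10)
        pd.testing.assert_frame_equal(out1, out2.reset_index(drop=True))

    def test_zero_mean_pair_dropped(self):
        scores = self._scores({"Z": [0, 0, 0, 0], "OK": [1, 2, 1, 2]})
        out = specificity_filter(scores, top_n=10)
        assert list(out["pair_id"]) == ["OK"]
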