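import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from subtme.discovery import SubTMEModule
from subtme.exceptions import EmptyResultError, EmptySignatureError, ValidationError
from subtme.scoring import (
    SsgseaParams,
    build_subtype_signature,
    bulk_subtme_score,
    expressing_fraction,
    signature_gene_score,
    ssgsea_matrix,
    ssgsea_score,
    subtme_score,
)

from conftest import make_em, simple_annotation


# ---------------------------------------------------------------- oracles

def bruteforce_fraction(xin, xout):
    """Independent quantile + count oracle for (Pgi, Qgi).

    Lower quartile of nonzero in-subtype values by explicit linear
    interpolation between sorted order statistics; counts by loops.
    """
    nz = sorted(v for v in xin if v > 0)
    if not nz:
        return None
    h = 0.25 * (len(nz) - 1)
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    t = nz[lo] + (h - lo) * (nz[hi] - nz[lo])
    p = sum(1 for v in xin if v > t) / len(xin)
    q = sum(1 for v in xout if v > t) / len(xout)
    return p, q, t


def bruteforce_ssgsea(expr: pd.Series, gene_set, alpha=0.25):
    """Two-loop ssGSEA oracle: explicit ECDF running sums."""
    items = sorted(expr.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    in_flags = [g in gene_set for g, _ in items]
    w = [(n - i) ** alpha if in_flags[i] else 0.0 for i in range(n)]
    wsum = sum(w)
    n_out = sum(1 for f in in_flags if not f)
    total = 0.0
    cin = cout = 0.0
    for i in range(n):
        if in_flags[i]:
            cin += w[i] / wsum
        else:
            cout += 1.0 / n_out
        total += cin - cout
    return total


# ------------------------------------------------------- expressing fraction

class TestExpressingFraction:
    def test_worked_quartile_example(self):
        # subtype nonzero values {1,2,3,4}: t = 1.75 by linear interpolation,
        # and the three cells at 2, 3, 4 exceed it (brute-force oracle agrees)
        X = np.array([[1, 2, 3, 4, 0, 0]])
        m = make_em(X.astype(float))
        m.normalized = m.counts.astype(float)
        ann = simple_annotation(list(m.obs), ["A"] * 4 + ["B"] * 2)
        frac = expressing_fraction(m, ann, "G1", "A")
        assert frac.threshold == pytest.approx(1.75)
        oracle = bruteforce_fraction([1, 2, 3, 4], [0, 0])
        assert frac.p == pytest.approx(oracle[0]) == 0.75
        assert frac.q == 0.0

    def test_gene_silent_in_subtype_is_ineligible(self):
        X = np.array([[0, 0, 5, 5]])
        m = make_em(X.astype(float))
        m.normalized = m.counts.astype(float)
        ann = simple_annotation(list(m.obs), ["A", "A", "B", "B"])
        frac = expressing_fraction(m, ann, "G1", "A")
        assert not frac.eligible and frac.p == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_genes, n_cells = rng.integers(3, 20), rng.integers(10, 80)
            X = rng.poisson(1.0, size=(n_genes, n_cells)).astype(float)
            m = make_em(X)
            m.normalized = m.counts.astype(float)
            labels = rng.choice(["A", "B", "C"], size=n_cells)
            labels[:3] = "A"
            ann = simple_annotation(list(m.obs), labels)
            in_mask = labels == "A"
            for gi, gene in enumerate(m.genes):
                expected = bruteforce_fraction(X[gi, in_mask], X[gi, ~in_mask])
                got = expressing_fraction(m, ann, gene, "A")
                if expected is None:
                    assert not got.eligible
                else:
                    assert got.p == pytest.approx(expected[0], abs=0)
                    assert got.q == pytest.approx(expected[1], abs=0)


class TestSignatureGeneScore:
    @pytest.mark.parametrize(
        "p,q,expected",
        [(0.8, 0.2, 0.75), (0.5, 0.0, 1.0), (0.9, 0.0, 1.0), (0.5, 0.5, 0.0), (0.2, 0.4, -1.0)],
    )
    def test_worked_values(self, p, q, expected):
        assert signature_gene_score(p, q) == pytest.approx(expected)

    def test_undefined_for_zero_p(self):
        with pytest.raises(ValidationError):
            signature_gene_score(0.0, 0.1)

    @given(
        p=st.floats(0.05, 1.0), q=st.floats(0.01, 0.95), dq=st.floats(0.01, 0.05),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monotone_in_p_and_q(self, p, q, dq):
        if q + dq <= 1:
            assert signature_gene_score(p, q + dq) < signature_gene_score(p, q)
        if p + dq <= 1 and q > 0:
            assert signature_gene_score(p + dq, q) > signature_gene_score(p, q)


class TestBuildSubtypeSignature:
    def test_planted_marker_selected_and_housekeeping_rejected(self, default_cohort):
        cfg, m, ann = default_cohort
        sig = build_subtype_signature(m, ann, "Myeloid_2")
        assert set(cfg.marker_genes("Myeloid_2")) <= set(sig.genes)
        assert not any(g.startswith("BG-") for g in sig.genes)
        # analytic expectation: Sgi ~ 1 - p_out/p_in for a planted marker
        sel = sig.gene_scores.set_index("gene")
        expect = 1 - cfg.marker_spec.p_out / cfg.marker_spec.p_in
        for g in cfg.marker_genes("Myeloid_2"):
            assert sel.loc[g, "Sgi"] == pytest.approx(expect, abs=0.12)

    def test_no_passing_gene_is_empty_signature_error(self):
        rng = np.random.default_rng(13)
        m = make_em(rng.poisson(2.0, size=(10, 60)), normalized=True)
        ann = simple_annotation(list(m.obs), ["A"] * 30 + ["B"] * 30)
        with pytest.raises(EmptySignatureError, match="A"):
            build_subtype_signature(m, ann, "A")

    def test_min_cells_guard(self, default_cohort):
        _, m, ann = default_cohort
        with pytest.raises(ValidationError):
            build_subtype_signature(m, ann, "Lymphoid_1", min_cells=10**6)


class TestSubtmeScore:
    def _abundance(self, rows):
        return pd.DataFrame(rows).set_index("sample_id")

    def test_worked_arithmetic(self):
        ab = self._abundance([{"sample_id": "S1", "A": 0.5, "B": 0.5}])
        out = subtme_score({"A": 0.8, "B": 0.6}, ab, SubTMEModule("M", ["A", "B"]))
        assert out.loc[0, "score"] == pytest.approx(0.35)

    def test_singleton_module(self):
        ab = self._abundance([{"sample_id": "S1", "A": 0.4}])
        out = subtme_score({"A": 0.8}, ab, SubTMEModule("M", ["A"]))
        assert out.loc[0, "score"] == pytest.approx(0.32)

    def test_missing_abundance_skipped_with_reduced_n(self):
        ab = self._abundance([{"sample_id": "S1", "A": np.nan, "B": 0.5}])
        out = subtme_score({"A": 0.8, "B": 0.6}, ab, SubTMEModule("M", ["A", "B"]))
        assert out.loc[0, "score"] == pytest.approx(0.3)
        assert out.loc[0, "n_subtypes_skipped"] == 1

    def test_all_missing_gives_missing_score(self):
        ab = self._abundance([{"sample_id": "S1", "A": np.nan}])
        out = subtme_score({"A": 0.8}, ab, SubTMEModule("M", ["A"]))
        assert np.isnan(out.loc[0, "score"])

    def test_monotone_in_abundance_of_better_subtype(self):
        mod = SubTMEModule("M", ["A", "B"])
        scores = []
        for pa in (0.2, 0.4, 0.6):
            ab = self._abundance([{"sample_id": "S1", "A": pa, "B": 0.3}])
            scores.append(subtme_score({"A": 0.9, "B": 0.5}, ab, mod).loc[0, "score"])
        assert scores == sorted(scores)


class TestSsgsea:
    def test_top_expressed_set_scores_positive(self):
        expr = pd.Series(np.arange(100, 0, -1, dtype=float), index=[f"g{i:03d}" for i in range(100)])
        assert ssgsea_score(expr, {"g000", "g001", "g002"}) > 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n = int(rng.integers(30, 120))
            expr = pd.Series(
                rng.poisson(3.0, size=n).astype(float), index=[f"g{i:04d}" for i in range(n)]
            )
            gene_set = set(rng.choice(expr.index, size=int(rng.integers(3, 10)), replace=False))
            got = ssgsea_score(expr, gene_set, SsgseaParams(normalization="none"))
            assert got == pytest.approx(bruteforce_ssgsea(expr, gene_set), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        expr = pd.Series(rng.random(200), index=[f"g{i:03d}" for i in range(200)])
        gene_set = set(rng.choice(expr.index, 20, replace=False))
        a = ssgsea_score(expr, gene_set)
        b = ssgsea_score(np.exp(5 * expr), gene_set)
        assert a == pytest.approx(b, abs=1e-12)

    def test_random_sets_score_between_bottom_and_top_sets(self):
        # the rank-weighted running sum orders set position faithfully:
        # bottom-expressed < random < top-expressed. (With alpha > 0 the
        # statistic has a positive offset under random sets, so it is not
        # zero-centered; the ordering is the meaningful null calibration.)
        rng = np.random.default_rng(16)
        expr = pd.Series(rng.random(2000), index=[f"g{i:05d}" for i in range(2000)])
        ranked = expr.sort_values(ascending=False).index
        top = ssgsea_score(expr, set(ranked[:50]))
        bottom = ssgsea_score(expr, set(ranked[-50:]))
        random_scores = [
            ssgsea_score(expr, set(rng.choice(expr.index, 50, replace=False)))
            for _ in range(100)
        ]
        assert bottom < min(random_scores) <= max(random_scores) < top

    def test_whole_universe_set_is_error(self):
        expr = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with pytest.raises(ValidationError):
            ssgsea_score(expr, {"a", "b", "c"})

    def test_matrix_range_normalization_preserves_order(self):
        rng = np.random.default_rng(17)
        expr = pd.DataFrame(
            rng.random((50, 6)), index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
        sets = {"A": [f"g{i}" for i in range(5)], "B": [f"g{i}" for i in range(5, 12)]}
        raw = ssgsea_matrix(expr, sets, SsgseaParams(normalization="none"))
        nrm = ssgsea_matrix(expr, sets, SsgseaParams(normalization="range"))
        rng_val = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(nrm.to_numpy(), raw.to_numpy() / rng_val)


class TestBulkSubtmeScore:
    def test_single_signature_module_equals_ssgsea(self):
        rng = np.random.default_rng(18)
        bulk = make_em(rng.poisson(5, size=(40, 3)), normalized=True)
        genes = list(bulk.genes[:5])
        out = bulk_subtme_score(bulk, {"A": genes}, SsgseaParams(normalization="none"))
        expr = bulk.to_frame("normalized")
        for _, row in out.iterrows():
            expected = ssgsea_score(expr[row["sample_id"]], genes, SsgseaParams(normalization="none"))
            assert row["score"] == pytest.approx(expected)

    def test_insufficient_overlap_skipped_then_error(self):
        rng = np.random.default_rng(19)
        bulk = make_em(rng.poisson(5, size=(20, 3)), normalized=True)
        sigs = {"A": list(bulk.genes[:4]), "B": ["NOPE1", "NOPE2"]}
        out = bulk_subtme_score(bulk, sigs)
        assert (out["n_signatures"] == 1).all()
        with pytest.raises(EmptyResultError):
            bulk_subtme_score(bulk, {"B": ["NOPE1", "NOPE2"]})
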