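"""Top-K/CMC metrics against brute-force oracles; closed-form statistical tests."""

import numpy as np
import pytest
from scipy import stats

from scoutreid.evaluate import (
    EvalReport,
    cmc_curve,
    mcnemar_test,
    score_distributions,
    stratified_eval,
    topk_accuracy,
    two_proportion_ztest,
)
from scoutreid.matcher import SimilarityMatrix


def brute_force_topk(S, ql, gl, k):
    """Independent oracle: full sort per query."""
    hits = 0
    for i, lab in enumerate(ql):
        order = sorted(range(len(gl)), key=lambda j: (-S[i, j], j))
        hits += lab in [gl[j] for j in order[:k]]
    return hits / len(ql)


class TestTopK:
    def test_simple_aligned_cases(self):
        gl = np.array(["a", "b"])
        S = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert topk_accuracy(S, gl, gl, 1) == 1.0
        S2 = np.array([[0.1, 0.9], [0.2, 0.8]])
        assert topk_accuracy(S2, gl, gl, 1) == 0.5
        assert topk_accuracy(S2, gl, gl, 2) == 1.0

    def test_full_gallery_exhaustion(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(-1, 1, size=(5, 5))
        labs = np.arange(5)
        assert topk_accuracy(S, labs, labs, 5) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        """100 random 20 x 15 similarity matrices vs an independent full-sort oracle."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            gl = np.arange(15)
            ql = rng.integers(0, 15, size=20)
            S = rng.uniform(-1, 1, size=(20, 15))
            for k in (1, 5, 15):
                assert topk_accuracy(S, ql, gl, k) == brute_force_topk(S, ql, gl, k)

    def test_unenrolled_query_excluded_and_warned(self):
        S = np.array([[0.9, 0.1], [0.5, 0.5]])
        gl = np.array(["a", "b"])
        ql = np.array(["a", "z"])  # z not enrolled
        with pytest.warns(UserWarning, match="not enrolled"):
            acc = topk_accuracy(S, ql, gl, 1)
        assert acc == 1.0

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            topk_accuracy(np.ones((1, 2)), ["a"], ["a", "b"], 0)


class TestCMC:
    def test_monotone_and_terminal_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            labs = np.arange(12)
            S = rng.uniform(-1, 1, size=(12, 12))
            cmc = cmc_curve(S, labs, labs)
            assert np.all(np.diff(cmc) >= 0)
            assert cmc[-1] == 1.0

    def test_first_element_equals_acc1(self):
        rng = np.random.default_rng(2)
        labs = np.arange(10)
        S = rng.uniform(-1, 1, size=(10, 10))
        assert cmc_curve(S, labs, labs)[0] == topk_accuracy(S, labs, labs, 1)


class TestScoreDistributions:
    def test_perfect_embeddings_give_genuine_one(self):
        S = np.eye(4) * 2 - 1  # genuine diag at 1, impostors at -1
        labs = np.arange(4)
        d = score_distributions(S, labs, labs)
        assert d["genuine_mean"] == 1.0 and d["impostor_mean"] == -1.0
        assert not d["overlap"]

    def test_random_unit_vectors_impostor_mean_near_zero(self):
        """For random directions in D=64, cos similarity has mean 0, var 1/D."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 64))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        Y = rng.normal(size=(50, 64))
        Y /= np.linalg.norm(Y, axis=1, keepdims=True)
        S = X @ Y.T
        d = score_distributions(S, np.arange(50), np.arange(50))
        # impostor entries are ~independent cosines: mean 0, var 1/D
        se = 1.0 / np.sqrt(64 * d["impostor_n"] / 10)  # conservative (rows correlated)
        assert abs(d["impostor_mean"]) < 3 * se * 10

    def test_counts_conserved(self):
        rng = np.random.default_rng(4)
        S = rng.uniform(-1, 1, size=(6, 4))
        d = score_distributions(S, np.arange(6) % 4, np.arange(4))
        assert d["genuine_n"] + d["impostor_n"] == 24

    def test_no_impostors_rejected(self):
        with pytest.raises(ValueError, match="impostor"):
            score_distributions(np.ones((1, 1)), ["a"], ["a"])


class TestStratified:
    def _make_sm(self):
        # 4 queries, 3 gallery patients; vendors set up for 2 same / 2 cross
        S = np.array(
            [
                [0.9, 0.1, 0.0],
                [0.2, 0.8, 0.0],
                [0.1, 0.6, 0.3],
                [0.0, 0.1, 0.9],
            ]
        )
        return SimilarityMatrix(
            S,
            query_ids=np.array(["a", "b", "c", "c"]),
            gallery_ids=np.array(["a", "b", "c"]),
            query_vendors=np.array(["S", "G", "S", "G"]),
            gallery_vendors=np.array(["S", "G", "G"]),
        )

    def test_subset_counts_sum_to_total(self):
        rep = stratified_eval(self._make_sm())
        assert sum(c["n"] for c in rep.cells.values()) == rep.n_queries
        assert rep.same_vendor["n"] + rep.different_vendor["n"] == rep.n_queries

    def test_pooled_groups_match_direct_recomputation(self):
        sm = self._make_sm()
        rep = stratified_eval(sm)
        # baseline vendors: a->S, b->G, c->G; so same-vendor queries are
        # 0 (a: S vs S), 1 (b: G vs G), 3 (c: G vs G); different is 2 (c: S vs G)
        direct = topk_accuracy(sm.values[[0, 1, 3]], ["a", "b", "c"], sm.gallery_ids, 1)
        assert rep.same_vendor["acc1"] == direct
        direct_diff = topk_accuracy(sm.values[[2]], ["c"], sm.gallery_ids, 1)
        assert rep.different_vendor["acc1"] == direct_diff

    def test_single_vendor_cohort_reports_empty_different_group(self):
        S = np.array([[0.9, 0.1], [0.2, 0.8]])
        sm = SimilarityMatrix(
            S,
            query_ids=np.array(["a", "b"]),
            gallery_ids=np.array(["a", "b"]),
            query_vendors=np.array(["S", "S"]),
            gallery_vendors=np.array(["S", "S"]),
        )
        rep = stratified_eval(sm)
        assert rep.different_vendor["n"] == 0
        assert np.isnan(rep.different_vendor["acc1"])

    def test_error_list_contains_failing_query(self):
        rep = stratified_eval(self._make_sm(), error_k=1)
        failing = {e["query"] for e in rep.errors}
        assert "c" in failing  # query 2 ranks its own patient below top-1


class TestZTest:
    def test_equal_proportions_give_zero_z(self):
        r = two_proportion_ztest(5, 10, 50, 100)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_to_1e10(self):
        """Pooled Z = (p1-p2)/sqrt(phat(1-phat)(1/n1+1/n2)), two-sided normal p."""
        cases = [(824, 887, 347, 404), (30, 40, 25, 50), (1, 10, 9, 10)]
        for k1, n1, k2, n2 in cases:
            r = two_proportion_ztest(k1, n1, k2, n2)
            phat = (k1 + k2) / (n1 + n2)
            z = (k1 / n1 - k2 / n2) / np.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
            p = 2 * stats.norm.sf(abs(z))
            assert r.statistic == pytest.approx(z, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_swapping_groups_flips_sign(self):
        a = two_proportion_ztest(30, 40, 25, 50)
        b = two_proportion_ztest(25, 50, 30, 40)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r = two_proportion_ztest(0, 10, 0, 20)
        assert r.p_value == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(11, 10, 1, 5)


class TestMcNemar:
    def test_closed_form_with_continuity_correction(self):
        # chi2 = (|b-c|-1)^2/(b+c): b=c=10 -> 0.05 ; b=5,c=15 -> 4.05
        r = mcnemar_test(10, 10, exact="never")
        assert r.statistic == pytest.approx(0.05, abs=1e-10)
        r2 = mcnemar_test(5, 15, exact="never")
        assert r2.statistic == pytest.approx(4.05, abs=1e-10)
        assert r2.p_value == pytest.approx(stats.chi2.sf(4.05, 1), abs=1e-10)

    def test_exact_binomial_for_small_counts(self):
        r = mcnemar_test(2, 8)  # b+c < 25 -> exact by default
        assert r.method.startswith("mcnemar exact")
        assert r.p_value == pytest.approx(2 * stats.binom.cdf(2, 10, 0.5), abs=1e-10)

    def test_symmetric_counts_maximize_p(self):
        total = 30
        p_sym = mcnemar_test(15, 15, exact="never").p_value
        for b in (0, 5, 10, 14):
            assert mcnemar_test(b, total - b, exact="never").p_value <= p_sym + 1e-12

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ValueError, match="discordant"):
            mcnemar_test(0, 0)
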