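"""Dual-criterion enhancer-calling statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from exonhancer import (
    EnhancerActivityModel,
    ExpressionMatrix,
    call_anatomies,
    classify,
    expression_proportions,
    fold_ratio,
    partition_ranksum,
    proportions_test,
    rank_sum_greater,
    reconstruct_count,
    round_half_up,
    simulate_embryos,
    table1_spec,
)
from exonhancer import datasets
from exonhancer.synthetic import EmbryoSimSpec

from conftest import random_matrix


class TestProportions:
    def test_all_zero_matrix(self, vocab):
        m = ExpressionMatrix("z", np.zeros((100, 10), dtype=np.uint8), vocab)
        assert (expression_proportions(m)["p_hat"] == 0).all()

    def test_forebrain_fraction_matches_reported(self, vocab):
        # 32 of 39 embryos forebrain-positive
        data = np.zeros((39, 10), dtype=np.uint8)
        data[:32, 0] = 1
        m = ExpressionMatrix("odz3", data, vocab)
        assert expression_proportions(m).loc["Forebrain", "p_hat"] == pytest.approx(0.8205, abs=5e-5)

    def test_empty_matrix_rejected(self, vocab):
        with pytest.raises(ValueError):
            expression_proportions(ExpressionMatrix("e", np.empty((0, 10)), vocab))

    def test_reconstruct_exact_cell(self):
        k, _, exact = reconstruct_count(0.8205, 39)
        assert (k, exact) == (32, True)

    def test_reconstruct_flags_non_invertible_cell(self):
        # 0.1610 is not any k/161 to 4 decimals; nearest is 26 (0.1615)
        k, residual, exact = reconstruct_count(0.1610, 161)
        assert k == 26 and not exact and abs(residual) < 1 / (2 * 161)


class TestProportionsTest:
    def test_equality_gives_half(self):
        assert proportions_test(10, 50, 20, 100) == pytest.approx(0.5)

    def test_far_below_control_gives_one(self):
        # construct 0/43 vs control 51/161
        assert proportions_test(0, 43, 51, 161) == pytest.approx(1.0, abs=1e-3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportions_test(0, 0, 5, 10)

    @given(st.integers(0, 2**30))
    def test_matches_yates_chi_squared_oracle(self, seed):
        """The signed-z path must agree with an independent Yates chi-squared."""
        rng = np.random.default_rng(seed)
        n1, n0 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
        k1, k0 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n0 + 1))
        if k1 + k0 == 0 or k1 + k0 == n1 + n0:
            return  # degenerate pooled proportion: no chi-squared defined
        table = np.array([[k1, n1 - k1], [k0, n0 - k0]])
        chi2 = stats.chi2_contingency(table, correction=True)
        p_two = proportions_test(k1, n1, k0, n0, alternative="two-sided")
        assert p_two == pytest.approx(chi2.pvalue, rel=1e-10, abs=1e-12)
        # one-sided halves the two-sided p on the favoured side
        p_g = proportions_test(k1, n1, k0, n0, alternative="greater")
        if k1 / n1 > k0 / n0:
            assert p_g == pytest.approx(chi2.pvalue / 2, rel=1e-10, abs=1e-12)
        else:
            assert p_g >= 0.5


class TestRankSum:
    def test_complete_separation_attains_minimum(self):
        # 5-vs-5: most extreme split has p = 1/C(10,5)
        assert rank_sum_greater([1.0] * 5, [0.0] * 5) == pytest.approx(1 / 252)

    def test_tie_free_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            expected = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            assert rank_sum_greater(x, y) == pytest.approx(expected)

    def test_tied_data_matches_permutation_oracle(self):
        """With heavy ties, the exact enumeration must agree with a label-shuffle
        Monte-Carlo null computed from scratch."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            pooled = rng.choice([0.0, 0.2, 0.4], size=10)
            x, y = pooled[:5], pooled[5:]
            p = rank_sum_greater(x, y)
            w_obs = stats.rankdata(np.concatenate([x, y]))[:5].sum()
            hits = 0
            n_mc = 20000
            for _ in range(n_mc):
                perm = rng.permutation(pooled)
                w = stats.rankdata(perm)[:5].sum()
                hits += w >= w_obs - 1e-9
            assert p == pytest.approx(hits / n_mc, abs=4 * np.sqrt(p * (1 - p) / n_mc) + 1e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_greater([], [1.0])


class TestPartitionRankSum:
    def test_deterministic_and_order_invariant_under_seed(self, control_matrix):
        m = random_matrix(9, n=60)
        p1 = partition_ranksum(m, control_matrix, "Forebrain", seed=3)
        p2 = partition_ranksum(m, control_matrix, "Forebrain", seed=3)
        assert p1 == p2
        shuffled = ExpressionMatrix(
            m.construct_id, m.data[::-1].copy(), m.vocabulary, batch_ids=m.batch_ids[::-1]
        )
        assert partition_ranksum(shuffled, control_matrix, "Forebrain", seed=3) == p1

    def test_saturated_vs_silent_is_minimal_every_run(self, vocab):
        ones = ExpressionMatrix("on", np.ones((50, 10), dtype=np.uint8), vocab)
        zeros = ExpressionMatrix("off", np.zeros((50, 10), dtype=np.uint8), vocab)
        for seed in (0, 1, 2):
            assert partition_ranksum(ones, zeros, "Eye", seed=seed) == pytest.approx(1 / 252)

    def test_too_many_partitions_rejected(self, control_matrix):
        tiny = random_matrix(2, n=3)
        with pytest.raises(ValueError, match="partition"):
            partition_ranksum(tiny, control_matrix, "Eye", n_partitions=5)

    def test_unknown_anatomy_rejected(self, control_matrix):
        with pytest.raises(KeyError):
            partition_ranksum(random_matrix(1), control_matrix, "Gills")


class TestDecisions:
    def test_reported_table_decisions_reproduced(self):
        """The dual rule recovers exactly the marked cells of the example table."""
        df = datasets.table1_frame()
        called = call_anatomies(
            df.set_index(["construct_id", "anatomy"])["p_prop"],
            df.set_index(["construct_id", "anatomy"])["p_ranksum"],
        )
        assert called["significant"].sum() == 8
        assert (called["significant"] == df.set_index(["construct_id", "anatomy"])["marked"]).all()

    def test_near_miss_cell_rejected(self):
        # one criterion at 0.0524 fails the conjunction
        out = call_anatomies({"Muscle": 0.0146}, {"Muscle": 0.0524})
        assert not out.loc["Muscle", "significant"]

    def test_alpha_monotonicity(self):
        out_05 = call_anatomies({"a": 0.04}, {"a": 0.06}, alpha=0.05)
        out_10 = call_anatomies({"a": 0.04}, {"a": 0.06}, alpha=0.10)
        assert not out_05.loc["a", "significant"] and out_10.loc["a", "significant"]

    @given(st.integers(0, 2**30))
    def test_shrinking_alpha_never_enlarges_call_set(self, seed):
        rng = np.random.default_rng(seed)
        p1 = dict(zip("abcde", rng.random(5)))
        p2 = dict(zip("abcde", rng.random(5)))
        big = set(call_anatomies(p1, p2, alpha=0.1).query("significant").index)
        small = set(call_anatomies(p1, p2, alpha=0.02).query("significant").index)
        assert small <= big

    def test_fold_ratios(self):
        assert round_half_up(fold_ratio(0.8205, 0.3354)) == 2.4
        assert round_half_up(fold_ratio(0.6875, 0.1800)) == 3.8
        assert fold_ratio(0.5, 0.5) == 1.0
        assert np.isnan(fold_ratio(0.3, 0.0))

    def test_classification_scheme(self):
        sig = classify("c", ("Eye", "Heart", "Muscle"), 0.60)
        assert (sig.activity_class, sig.specificity) == ("significant", "specific")
        none = classify("c", (), 0.03)
        assert (none.activity_class, none.specificity) == ("none", "not-applicable")
        nonspec = classify("c", tuple("abcde"), 0.80)
        assert nonspec.specificity == "nonspecific"
        weak = classify("c", (), 0.30)
        assert (weak.activity_class, weak.specificity) == ("weak", "not-applicable")


class TestModel:
    def test_planted_effect_recovered(self, control_matrix):
        """A notochord effect at reported effect size is called; null anatomies are not."""
        probs = [datasets.CONTROL_PROPORTIONS[a] for a in datasets.ANATOMIES]
        probs[5] = 0.60  # notochord planted high vs control 0.16
        spec = EmbryoSimSpec(n_embryos=53, anatomy_probs=probs, construct_id="planted", seed=21)
        cce, _ = simulate_embryos(spec)
        res = EnhancerActivityModel(cce, control_matrix).fit(seed=2)
        assert "Notochord" in res.significant_anatomies
        assert len(res.significant_anatomies) <= 2
        assert res.call.activity_class == "significant"

    def test_summary_mentions_call(self, control_matrix):
        res = EnhancerActivityModel(random_matrix(3, n=40), control_matrix).fit(seed=0)
        text = res.summary()
        assert "Activity class" in text and "rand" in text

    def test_vocabulary_mismatch_rejected(self, control_matrix):
        from exonhancer.vocab import AnatomyVocabulary, DEFAULT_VOCABULARY

        small = AnatomyVocabulary(DEFAULT_VOCABULARY.entries[:5])
        m = ExpressionMatrix("s", np.zeros((10, 5), dtype=np.uint8), small)
        with pytest.raises(ValueError, match="vocabulary"):
            EnhancerActivityModel(m, control_matrix)
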