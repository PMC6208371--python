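import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sensiscreen.hit_calling import (
    HitCallConfig,
    MimicResult,
    benjamini_hochberg,
    class_counts,
    classify,
    pooled_t_test,
    rank_sensitizers,
    score_screen,
)
from sensiscreen.synthetic_data import GeneratorConfig, simulate_screen


class TestPooledT:
    def test_identical_groups(self):
        t, df, p = pooled_t_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert (t, p) == (0.0, 1.0)
        assert df == 4

    def test_hand_formula(self):
        """a=(1,2,3), b=(2,3,4): pooled s^2 = 1, se = sqrt(2/3)."""
        t, df, p = pooled_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.0 / math.sqrt(2.0 / 3.0))
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(1.2247, 4), abs=1e-4)
        assert p == pytest.approx(0.2878, abs=1e-3)

    def test_degenerate_variance_sentinels(self):
        t, _, p = pooled_t_test([2.0, 2.0], [1.0, 1.0])
        assert t == math.inf and p == 0.0
        t, _, p = pooled_t_test([1.0, 1.0], [2.0, 2.0])
        assert t == -math.inf and p == 0.0

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(loc=0.3, size=rng.integers(2, 8))
            t, df, p = pooled_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_type_i_error_near_nominal_on_null_generator_noise(self, rng):
        """Lognormal CV-5% nulls at n=3 per arm reject ~alpha of the time."""
        sigma = math.sqrt(math.log(1 + 0.05**2))
        n_sim, alpha = 4000, 0.05
        rejections = 0
        for _ in range(n_sim):
            a = rng.lognormal(-sigma**2 / 2, sigma, 3)
            b = rng.lognormal(-sigma**2 / 2, sigma, 3)
            rejections += pooled_t_test(a, b)[2] < alpha
        rate = rejections / n_sim
        assert rate == pytest.approx(alpha, abs=3 * math.sqrt(alpha * (1 - alpha) / n_sim) + 0.005)


def bh_bruteforce(p, q):
    """Independent step-up oracle: scan every k; q_i = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    qvals = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        qvals[order[i]] = running
    return qvals, reject


class TestBenjaminiHochberg:
    def test_all_ones_reject_nothing(self):
        q, rej = benjamini_hochberg(np.ones(10), 0.05)
        assert not rej.any()
        assert (q == 1.0).all()

    def test_worked_example(self):
        """p = (.01, .02, .03, .5) at Q = 0.05: the step-up keeps the first 3."""
        q, rej = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]), 0.05)
        assert rej.sum() == 3
        assert rej.tolist() == [True, True, True, False]

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        q=st.sampled_from([0.005, 0.01, 0.05, 0.25]),
    )
    @settings(deadline=None, max_examples=80)
    def test_matches_bruteforce_oracle(self, ps, q):
        p = np.array(ps)
        qv, rej = benjamini_hochberg(p, q)
        qv_ref, rej_ref = bh_bruteforce(p, q)
        np.testing.assert_allclose(qv, qv_ref, rtol=1e-12)
        np.testing.assert_array_equal(rej, rej_ref)

    def test_matches_bruteforce_at_m_2000(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-3, 100), rng.uniform(0, 1, 1900)])
        qv, rej = benjamini_hochberg(p, 0.005)
        qv_ref, rej_ref = bh_bruteforce(p, 0.005)
        np.testing.assert_allclose(qv, qv_ref, rtol=1e-12)
        np.testing.assert_array_equal(rej, rej_ref)

    def test_rejections_monotone_in_q(self, rng):
        p = rng.uniform(0, 1, 200)
        counts = [benjamini_hochberg(p, q)[1].sum() for q in (0.001, 0.01, 0.05, 0.2, 0.5)]
        assert counts == sorted(counts)

    def test_nan_p_excluded(self):
        with pytest.warns(UserWarning, match="NaN"):
            q, rej = benjamini_hochberg(np.array([0.001, np.nan, 0.9]), 0.05)
        assert np.isnan(q[1]) and not rej[1]
        assert rej[0]

    def test_empty_input(self):
        q, rej = benjamini_hochberg(np.array([]), 0.05)
        assert q.size == 0 and rej.size == 0


def _result(entity, ratio, vehicle_change=0.0, p=1.0, vehicle_p=1.0):
    return MimicResult(
        entity=entity, mu_vehicle=1.0 + vehicle_change, mu_drug=ratio * (1.0 + vehicle_change),
        ratio=ratio, vehicle_change=vehicle_change, t_stat=0.0, df=4,
        p_value=p, vehicle_p=vehicle_p,
    )


class TestClassify:
    def test_vehicle_toxicity_trumps_ratio(self):
        """A +30% significant vehicle shift is drug-neutral whatever the ratio."""
        results = [_result(f"n{i}", 1.0) for i in range(99)]
        results.append(_result("tox", 0.4, vehicle_change=0.30, p=1e-9, vehicle_p=1e-4))
        out = classify(results)
        assert {r.hit_class for r in out if r.entity == "tox"} == {"drug_neutral"}

    def test_unit_ratio_no_vehicle_change_is_no_effect(self):
        out = classify([_result(f"n{i}", 1.0) for i in range(50)])
        assert all(r.hit_class == "no_effect" for r in out)

    def test_single_true_sensitizer_among_nulls(self):
        """Noiseless: ratio 0.6 with p=0 among 99 unit-ratio nulls is the one hit."""
        results = [_result(f"n{i}", 1.0) for i in range(99)]
        results.append(_result("hit", 0.6, p=0.0))
        out = classify(results)
        counts = class_counts(out)
        assert counts["sensitizer"] == 1
        assert [r.entity for r in out if r.hit_class == "sensitizer"] == ["hit"]

    def test_noiseless_screen_recovers_truth_exactly(self):
        cfg = GeneratorConfig(n_mimics=300, noise_cv=0.0, seed=13)
        ds, truth = simulate_screen(cfg)
        out = classify(score_screen(ds))
        called = {r.entity: r.hit_class for r in out}
        expected_map = {
            "sensitizer": "sensitizer",
            "desensitizer": "desensitizer",
            "vehicle_toxic": "drug_neutral",
            "null": "no_effect",
        }
        for entity, cls in zip(truth["entity"], truth["class"]):
            assert called[entity] == expected_map[cls], entity

    def test_hit_sets_are_disjoint(self, small_noisy_screen):
        ds, _ = small_noisy_screen
        out = classify(score_screen(ds))
        sens = {r.entity for r in out if r.hit_class == "sensitizer"}
        desens = {r.entity for r in out if r.hit_class == "desensitizer"}
        neutral = {r.entity for r in out if r.hit_class == "drug_neutral"}
        assert not (sens & desens)
        assert not (neutral & (sens | desens))
        assert len(out) == len(sens | desens | neutral
                               | {r.entity for r in out if r.hit_class == "no_effect"})

    def test_empirical_fdr_bounded_under_all_nulls(self):
        """An all-null screen at default noise calls (almost) no sensitizers."""
        cfg = GeneratorConfig(
            n_mimics=500, seed=17,
            fractions={"sensitizer": 0.0, "desensitizer": 0.0,
                       "vehicle_toxic": 0.0, "null": 1.0},
        )
        ds, _ = simulate_screen(cfg)
        out = classify(score_screen(ds))
        counts = class_counts(out)
        # expected false sensitizers <= Q * calls; with 500 nulls allow a couple
        assert counts["sensitizer"] + counts["desensitizer"] <= 2

    def test_small_screen_warns_on_percentile(self):
        with pytest.warns(UserWarning, match="percentile"):
            classify([_result(f"n{i}", 1.0) for i in range(10)])


class TestRanking:
    def test_orders_by_ratio_then_q(self):
        a = MimicResult("a", 1, 0.7, 0.7, 0, 0, 4, 0, q_value=0.004, hit_class="sensitizer")
        b = MimicResult("b", 1, 0.5, 0.5, 0, 0, 4, 0, q_value=0.004, hit_class="sensitizer")
        c = MimicResult("c", 1, 0.7, 0.7, 0, 0, 4, 0, q_value=0.001, hit_class="sensitizer")
        d = MimicResult("d", 1, 1.0, 1.0, 0, 0, 4, 1, q_value=1.0, hit_class="no_effect")
        assert [r.entity for r in rank_sensitizers([a, b, c, d])] == ["b", "c", "a"]

    def test_graded_spiked_effects_recovered_in_order(self):
        """Stronger true sensitizers rank ahead of weaker ones."""
        cfg = GeneratorConfig(n_mimics=200, noise_cv=0.0, seed=23)
        ds, truth = simulate_screen(cfg)
        ranked = rank_sensitizers(classify(score_screen(ds)))
        true_ratio = dict(zip(truth["entity"], truth["drug_ratio"]))
        ratios = [true_ratio[r.entity] for r in ranked]
        assert ratios == sorted(ratios)
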