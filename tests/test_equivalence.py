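"""Bootstrap difference testing, KS, Bonferroni and equivalence-range tests."""

import itertools

import numpy as np
import pytest

from sivar import (BlockSample, EquivalenceRange, ModelInputError,
                   bonferroni_threshold, bootstrap_median_diff, compare_block,
                   derive_equivalence_range, equivalence_range_profile,
                   equivalence_verdict, ks_two_sample)


class TestBootstrap:
    def test_degenerate_samples_give_point_interval(self):
        ci = bootstrap_median_diff(np.full(5, 7.0), np.full(8, 3.0), seed=1)
        assert ci.point == 4.0
        assert ci.ci95 == (4.0, 4.0) and ci.ci996 == (4.0, 4.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_identical_multisets_ci_contains_zero(self, seed):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 8.0, 9.0, 12.0])
        ci = bootstrap_median_diff(x, x.copy(), seed=seed)
        assert ci.ci95[0] <= 0.0 <= ci.ci95[1]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        x, y = rng.lognormal(size=50), rng.lognormal(size=60)
        a = bootstrap_median_diff(x, y, seed=123)
        b = bootstrap_median_diff(x, y, seed=123)
        assert a == b

    def test_ci_nesting_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            x = rng.lognormal(0, 1, rng.integers(5, 60))
            y = rng.lognormal(0.2, 1, rng.integers(5, 60))
            ci = bootstrap_median_diff(x, y, n_boot=300, seed=rng)
            assert ci.ci996[0] <= ci.ci95[0] and ci.ci95[1] <= ci.ci996[1]

    def test_percent_mode_definition(self):
        x = np.full(10, 6.0)
        y = np.full(10, 5.0)
        ci = bootstrap_median_diff(x, y, seed=0, mode="percent")
        assert ci.point == pytest.approx(20.0)
        with pytest.raises(ModelInputError, match="med\\(y\\)"):
            bootstrap_median_diff(x, np.zeros(5), seed=0, mode="percent")

    def test_small_samples_rejected(self):
        with pytest.raises(ModelInputError, match="n >= 2"):
            bootstrap_median_diff([1.0], [1.0, 2.0], seed=0)

    def test_coverage_of_known_median_shift(self):
        """Monte-Carlo coverage oracle: shifted lognormal pairs with a known
        true difference of medians; the 95% CI must cover it >= 90% of reps."""
        rng = np.random.default_rng(17)
        shift = 1.4
        true_delta = np.exp(0.0) * (shift - 1.0)
        hits = 0
        reps = 500
        for _ in range(reps):
            x = shift * rng.lognormal(0.0, 0.6, 200)
            y = rng.lognormal(0.0, 0.6, 200)
            ci = bootstrap_median_diff(x, y, n_boot=400, seed=rng)
            hits += ci.ci95[0] <= true_delta <= ci.ci95[1]
        assert hits / reps >= 0.90

    def test_null_false_positive_rate_near_nominal(self):
        """Under a true null at n=100 per arm the 95% CI excludes zero in
        about 5% of reps (99% binomial acceptance band)."""
        from scipy import stats

        rng = np.random.default_rng(23)
        reps, excl = 800, 0
        for _ in range(reps):
            x = rng.lognormal(0.0, 0.5, 100)
            y = rng.lognormal(0.0, 0.5, 100)
            ci = bootstrap_median_diff(x, y, n_boot=400, seed=rng)
            excl += not (ci.ci95[0] <= 0.0 <= ci.ci95[1])
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= excl <= hi


class TestKolmogorovSmirnov:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        assert ks_two_sample(x, x.copy()) == 1.0

    def test_disjoint_supports_give_tiny_p(self):
        p = ks_two_sample(np.arange(100.0), 1000.0 + np.arange(100.0))
        assert p < 1e-6

    def test_tiny_samples_match_permutation_enumeration(self):
        """n=3,3 without ties: p equals exact enumeration over all 20
        equally likely label assignments of the pooled sample."""
        x = np.array([0.3, 1.7, 2.2])
        y = np.array([0.9, 2.8, 4.1])

        def ks_stat(a, b):
            pooled = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
            return np.max(np.abs(fa - fb))

        d_obs = ks_stat(x, y)
        pooled = np.concatenate([x, y])
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(6) if i not in idx]]
            total += 1
            if ks_stat(a, b) >= d_obs - 1e-12:
                count += 1
        assert ks_two_sample(x, y) == pytest.approx(count / total, abs=1e-12)


class TestBonferroni:
    def test_study_family_of_twelve(self):
        a = bonferroni_threshold(0.05, 12)
        assert a == pytest.approx(0.05 / 12)
        assert f"{a:.3f}" == "0.004"

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.10, 4, 0.025)])
    def test_simple_families(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_family_size(self):
        with pytest.raises(ModelInputError):
            bonferroni_threshold(0.05, 0)


class TestEquivalenceRange:
    def test_zero_error_gives_zero_width(self):
        r = derive_equivalence_range(bg_error_sd=0.0, reference_bg=6.0)
        assert r.half_width == 0.0

    def test_width_non_decreasing_in_error_sd(self):
        widths = [derive_equivalence_range(bg_error_sd=sd, reference_bg=6.0).half_width
                  for sd in (0.0, 2.0, 5.0, 9.4, 14.0)]
        assert np.all(np.diff(widths) >= 0)

    def test_mid_band_width_in_low_teens(self):
        r = derive_equivalence_range(bg_error_sd=9.4, reference_bg=6.0)
        assert 10.0 <= r.half_width <= 15.0

    def test_width_varies_with_bg(self):
        prof = equivalence_range_profile(bg_grid=(4.4, 6.0, 8.0))
        w = prof["half_width_pct"].to_numpy()
        assert w[0] < w[1] < w[2]  # wider at higher BG


class TestVerdicts:
    def test_interval_inside_band_is_equivalent(self):
        r = EquivalenceRange(half_width=12.0, basis=9.4, reference_bg=6.0)
        assert equivalence_verdict((-5.0, 5.0), r)

    def test_interval_outside_band_is_not_equivalent(self):
        r = EquivalenceRange(half_width=12.0, basis=9.4, reference_bg=6.0)
        assert not equivalence_verdict((-20.0, -13.0), r)

    def test_cohort_bg_style_check(self):
        # a (2.6, 7.1) percent CI sits inside a +/-9.4 band
        r = EquivalenceRange(half_width=9.4, basis=9.4, reference_bg=5.8)
        assert equivalence_verdict((2.6, 7.1), r)

    def test_mirror_symmetry_of_equivalence_logic(self):
        r = EquivalenceRange(half_width=10.0, basis=9.4, reference_bg=6.0)
        rng = np.random.default_rng(6)
        for _ in range(200):
            lo, hi = np.sort(rng.uniform(-25, 25, 2))
            assert equivalence_verdict((lo, hi), r) == \
                equivalence_verdict((-hi, -lo), r)

    def test_swapping_arms_negates_point_estimate(self):
        rng = np.random.default_rng(7)
        x, y = rng.lognormal(0, 1, 40), rng.lognormal(0.3, 1, 50)
        a = bootstrap_median_diff(x, y, seed=1)
        b = bootstrap_median_diff(y, x, seed=1)
        assert a.point == -b.point


class TestCompareBlock:
    def make_pair(self, x, y, metric="si"):
        return (BlockSample(block=0, group="survivor", metric=metric, values=x),
                BlockSample(block=0, group="non-survivor", metric=metric, values=y))

    def test_identical_samples_not_significant_but_equivalent(self):
        rng = np.random.default_rng(10)
        v = rng.lognormal(-8, 0.4, 120)
        x, y = self.make_pair(v, v.copy())
        r = EquivalenceRange(half_width=12.0, basis=9.4, reference_bg=6.0)
        verdict = compare_block(x, y, r, seed=3)
        assert not verdict.difference_significant_95
        assert not verdict.significant_after_bonferroni
        assert verdict.equivalent and verdict.ks_p == 1.0

    def test_twenty_percent_scaled_arm_is_not_equivalent(self):
        rng = np.random.default_rng(12)
        base = rng.lognormal(-8, 0.4, 800)
        x, y = self.make_pair(base, 1.2 * base)
        r = EquivalenceRange(half_width=12.0, basis=9.4, reference_bg=6.0)
        verdict = compare_block(x, y, r, seed=4)
        assert verdict.diff_percent.point == pytest.approx(-16.67, abs=0.5)
        assert not verdict.equivalent
        assert verdict.difference_significant_95

    def test_bonferroni_significance_implies_95_significance(self):
        rng = np.random.default_rng(13)
        r = EquivalenceRange(half_width=12.0, basis=9.4, reference_bg=6.0)
        for _ in range(200):
            shift = rng.normal(0, 0.3)
            x, y = self.make_pair(rng.lognormal(shift, 0.5, 40),
                                  rng.lognormal(0, 0.5, 40))
            v = compare_block(x, y, r, n_boot=300, seed=rng)
            assert v.difference_significant_95 or not v.significant_after_bonferroni

    def test_empty_sample_rejected(self):
        x, y = self.make_pair(np.array([1.0, 2.0]), np.array([]))
        r = EquivalenceRange(half_width=12.0, basis=9.4, reference_bg=6.0)
        with pytest.raises(ModelInputError, match="empty"):
            compare_block(x, y, r, seed=0)
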