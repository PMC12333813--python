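"""dRE, slopes and the rank statistics against brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from visrsim.angles import (
    delta_re,
    midranks,
    slope_fit,
    spearman_rho,
    wilcoxon_ranksum,
)

ANGLES = np.array([90.0, 86.0, 78.0, 70.0, 66.0, 58.0, 46.0])


class TestDeltaRE:
    def test_constant_re_gives_zero(self):
        curve = delta_re(ANGLES, np.full((3, 7), 5e5))
        np.testing.assert_array_equal(curve.dre_pct, 0.0)

    def test_doubling_gives_hundred_percent(self):
        re = np.full((1, 7), 4e5)
        re[0, -1] = 8e5  # 46 degrees
        curve = delta_re(ANGLES, re)
        assert curve.dre_pct[0, -1] == pytest.approx(100.0)

    def test_reference_within_realization(self):
        re = np.array([[4e5, 4e5, 5e5, 4e5, 4e5, 4e5, 4e5],
                       [8e5, 8e5, 8e5, 8e5, 8e5, 8e5, 1.2e6]])
        curve = delta_re(ANGLES, re)
        assert curve.dre_pct[0, 2] == pytest.approx(25.0)
        assert curve.dre_pct[1, -1] == pytest.approx(50.0)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="90"):
            delta_re(ANGLES[1:], np.ones((2, 6)))


class TestSlopeFit:
    def test_flat_curve_zero_slope(self):
        curve = delta_re(ANGLES, np.full((2, 7), 5e5))
        est = slope_fit(curve)
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_two_point_line(self):
        angles = np.array([90.0, 46.0])  # deviations 0 and 44
        re = np.array([[4e5, 7.52e5]])  # dRE = 88%
        est = slope_fit(delta_re(angles, re))
        assert est.slope == pytest.approx(2.0, rel=1e-12)

    def test_seven_angle_sin2_curve_matches_ols_oracle(self):
        delta = 90.0 - ANGLES
        dre = 100 * 0.05 * 10.0 * np.sin(np.deg2rad(delta)) ** 2
        re = 4e5 * (1 + dre / 100.0)
        est = slope_fit(delta_re(ANGLES, re[None, :]))
        xc = delta - delta.mean()
        oracle = float(np.dot(xc, dre - dre.mean()) / np.dot(xc, xc))
        assert est.slope == pytest.approx(oracle, rel=1e-12)

    def test_single_angle_degenerate(self):
        with pytest.raises(ValueError, match="two distinct angles"):
            slope_fit(delta_re(np.array([90.0]), np.array([[1.0]])))

    def test_replicate_slopes_one_per_realization(self):
        rng = np.random.default_rng(0)
        re = 4e5 * (1 + rng.uniform(0, 0.5, size=(5, 7)))
        re[:, 0] = 4e5
        est = slope_fit(delta_re(ANGLES, re))
        assert est.replicate_slopes.shape == (5,)
        assert est.slope == pytest.approx(est.replicate_slopes.mean())


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks differ by d = (2, -1, -1): rho = 1 - 6*6/(3*8) = -0.5
        assert spearman_rho(np.array([1, 2, 3]), np.array([3, 1, 2])) == pytest.approx(-0.5)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rho_scipy = scipy.stats.spearmanr(x, y).statistic
        assert spearman_rho(x, y) == pytest.approx(rho_scipy, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=8),
        st.lists(st.integers(0, 5), min_size=3, max_size=8),
    )
    def test_matches_scipy_on_small_tied_inputs(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float)
        y = np.array(ys[:n], dtype=float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            return
        assert spearman_rho(x, y) == pytest.approx(
            scipy.stats.spearmanr(x, y).statistic, rel=1e-9, abs=1e-12
        )


def _brute_force_ranksum_p(a, b):
    """Independent enumeration oracle over all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n = len(a)
    mu = n * (len(pooled) + 1) / 2.0
    w_obs = ranks[:n].sum()
    stats = [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n)]
    return np.mean([abs(s - mu) >= abs(w_obs - mu) - 1e-12 for s in stats])


class TestWilcoxonRankSum:
    def test_identical_samples_not_separated(self):
        _, p, sig = wilcoxon_ranksum(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert p >= 0.99
        assert not sig

    def test_exact_small_example(self):
        _, p, _ = wilcoxon_ranksum(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1.0 / 3.0)

    def test_exact_fully_separated_tens(self):
        a = np.arange(1.0, 11.0)
        b = np.arange(11.0, 21.0)
        _, p, sig = wilcoxon_ranksum(a, b)
        assert p == pytest.approx(2.0 / 184756.0)
        assert sig

    def test_empty_or_singleton_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum(np.array([1.0]), np.array([2.0, 3.0]))

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=4),
        st.lists(st.integers(0, 6), min_size=2, max_size=4),
    )
    def test_matches_enumeration_oracle_small_inputs(self, xs, ys):
        a, b = np.array(xs, dtype=float), np.array(ys, dtype=float)
        _, p, _ = wilcoxon_ranksum(a, b)
        assert p == pytest.approx(_brute_force_ranksum_p(a, b), rel=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        a = rng.permutation(20)[:8].astype(float)
        b = (rng.permutation(20)[:8] + 0.5).astype(float)
        _, p, _ = wilcoxon_ranksum(a, b)
        p_scipy = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(p_scipy, rel=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(1.0, 1.0, 25)
        _, p, _ = wilcoxon_ranksum(a, b)
        p_scipy = scipy.stats.ranksums(a, b).pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)


def test_midranks_average_ties():
    np.testing.assert_array_equal(
        midranks(np.array([10.0, 20.0, 20.0, 30.0])), [1.0, 2.5, 2.5, 4.0]
    )
    np.testing.assert_array_equal(
        midranks(np.array([5.0, 5.0, 5.0])), [2.0, 2.0, 2.0]
    )
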