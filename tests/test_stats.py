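"""Outlier screening, test selection, correlation and stepwise entry."""

import itertools

import numpy as np
import pytest

from osteoquant.stats import (
    GroupSample,
    compare_groups,
    forward_stepwise,
    pearson_r,
    r_squared,
    remove_outliers,
    significance_stars,
)


class TestRemoveOutliers:
    def test_small_sample_unchanged(self):
        vals, removed = remove_outliers(np.array([1.0, 2.0, 3.0]))
        assert vals.tolist() == [1.0, 2.0, 3.0]
        assert removed == []

    def test_two_sd_rule_can_be_inert(self):
        """{0,0,0,0,10}: mean 2, SD 4.472; |10-2| = 8 < 8.944 -> kept."""
        vals, removed = remove_outliers(np.array([0.0, 0, 0, 0, 10.0]))
        assert vals.size == 5
        assert removed == []

    def test_extreme_point_removed(self):
        """Nine zeros and a 30: mean 3, SD 9.487; 27 > 18.97 -> removed."""
        data = np.array([0.0] * 9 + [30.0])
        vals, removed = remove_outliers(data)
        assert vals.size == 9
        assert removed == ["9"]

    def test_single_pass_not_iterated(self):
        # after removing 30, zero-SD would remove nothing more anyway;
        # but the pass must use the original mean/SD only once
        data = np.array([0.0] * 9 + [30.0, 19.0])
        vals, removed = remove_outliers(data)
        # sd of the full sample keeps 19 inside 2 SD
        assert 19.0 in vals

    def test_zero_sd_removes_nothing(self):
        vals, removed = remove_outliers(np.array([5.0, 5.0, 5.0]))
        assert removed == []


class TestCompareGroups:
    def test_identical_samples(self):
        a = GroupSample("x", "control", np.array([1.0, 2, 3, 4, 5]))
        b = GroupSample("x", "t2d", np.array([1.0, 2, 3, 4, 5]))
        res = compare_groups(a, b)
        assert res.percent_difference == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mann_whitney_matches_exhaustive_enumeration(self):
        """Exact U-test p equals the brute-force permutation distribution
        over all C(8,4) = 70 group labelings."""
        x = np.array([1.2, 3.4, 2.2, 5.1])
        y = np.array([2.9, 4.4, 6.0, 7.1])

        def u_stat(a, b):
            return sum(
                (ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b
            )

        pooled = np.concatenate([x, y])
        u_obs = u_stat(x, y)
        n = len(x)
        count = 0
        total = 0
        for combo in itertools.combinations(range(8), n):
            aa = pooled[list(combo)]
            bb = pooled[[i for i in range(8) if i not in combo]]
            u = u_stat(aa, bb)
            # two-sided: as or more extreme in either direction
            if min(u, n * n - u) <= min(u_obs, n * n - u_obs):
                count += 1
            total += 1
        p_oracle = count / total

        res = compare_groups(
            GroupSample("x", "control", x),
            GroupSample("x", "t2d", y),
            outlier_k=None,
        )
        # force the nonparametric branch for the comparison
        from osteoquant.stats import _mann_whitney_exact

        assert _mann_whitney_exact(x, y) == pytest.approx(p_oracle, abs=1e-12)
        del res

    def test_cortical_thickness_percent_difference(self):
        """Printed cortical thickness means 0.70 vs 0.61 -> 12.9%."""
        pct = (0.70 - 0.61) / 0.70 * 100.0
        assert pct == pytest.approx(12.9, abs=0.05)

    def test_group_swap_symmetry(self, rng):
        x = rng.normal(10, 2, 12)
        y = rng.normal(12, 2, 12)
        a = compare_groups(GroupSample("p", "control", x),
                           GroupSample("p", "t2d", y))
        b = compare_groups(GroupSample("p", "control", y),
                           GroupSample("p", "t2d", x))
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(
                GroupSample("p", "control", np.array([1.0, 2.0, 3.0])),
                GroupSample("p", "t2d", np.array([1.0])),
            )

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.5) == ""


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_r(np.arange(10.0), 3.0 * np.arange(10.0) + 1.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_r_squared_of_reported_correlation(self):
        """r = -0.697 explains 48.6% of variance."""
        assert r_squared(-0.697) == pytest.approx(0.486, abs=0.0005)

    def test_five_point_covariance_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r_oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(r_oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestForwardStepwise:
    def test_single_perfect_predictor(self):
        x = np.arange(20.0)
        model = forward_stepwise(2.0 * x, {"x": x})
        assert model.entered == ["x"]
        assert model.r_squared == pytest.approx(1.0)

    def test_only_informative_candidate_enters(self, rng):
        """y tracks c1 (r ~ 0.9); c2 is pure noise; only c1 enters, and it
        beats c2 in an exhaustive single-predictor comparison."""
        n = 50
        c1 = rng.normal(size=n)
        c2 = rng.normal(size=n)
        y = 0.9 * c1 + np.sqrt(1 - 0.81) * rng.normal(size=n)
        model = forward_stepwise(y, {"c1": c1, "c2": c2})
        assert model.entered == ["c1"]
        # exhaustive oracle: single-predictor correlation comparison
        r1, _ = pearson_r(c1, y)
        r2, _ = pearson_r(c2, y)
        assert abs(r1) > abs(r2)

    def test_alpha_one_orders_by_single_step_p(self, rng):
        n = 40
        c1 = rng.normal(size=n)
        c2 = rng.normal(size=n)
        y = 0.8 * c1 + 0.3 * c2 + 0.3 * rng.normal(size=n)
        model = forward_stepwise(y, {"c1": c1, "c2": c2}, alpha_enter=1.0)
        assert model.entered[0] == "c1"
        assert len(model.entered) == 2

    def test_collinear_candidate_skipped(self, rng):
        n = 30
        c1 = rng.normal(size=n)
        y = c1 + 0.1 * rng.normal(size=n)
        model = forward_stepwise(
            y, {"c1": c1, "c1_copy": c1 * 1.0000000001}, cond_max=1e6
        )
        assert model.entered == ["c1"]
        assert "c1_copy" in model.skipped

    def test_glycation_factor_recovers_reported_variance(self, rng):
        """A latent severity factor with loading 0.835 on NE-xLR and -0.835
        on PYD induces r ~ -0.697, so NE-xLR alone explains ~48.6% of PYD
        variance at large n."""
        n = 500
        g = rng.normal(size=n)
        lam = 0.835
        ne = lam * g + np.sqrt(1 - lam**2) * rng.normal(size=n)
        pyd = -lam * g + np.sqrt(1 - lam**2) * rng.normal(size=n)
        fage_noise = rng.normal(size=n)
        model = forward_stepwise(pyd, {"ne_xlr": ne, "fage": fage_noise})
        assert model.entered == ["ne_xlr"]
        assert model.r_squared == pytest.approx(0.486, abs=0.08)
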