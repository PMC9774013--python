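"""Archimedean copulas: rank transforms, empirical copula, family formulas,
conditional sampling and maximum-likelihood estimation."""

import numpy as np
import pytest
from scipy import optimize, stats

from ssacopula import copulas as cp

FAMILY_THETAS = [("clayton", 2.0), ("clayton", -0.5), ("frank", 5.0), ("frank", -3.0),
                 ("gumbel", 1.0), ("gumbel", 2.5)]


def brute_force_empirical_copula(u, v, a, b):
    """Oracle: explicit double loop over the defining indicator sum."""
    count = 0
    for ui, vi in zip(u, v):
        if ui <= a and vi <= b:
            count += 1
    return count / len(u)


class TestRankTransform:
    def test_three_distinct_values(self):
        assert np.allclose(cp.rank_transform([10.0, 20.0, 30.0]), [0.25, 0.5, 0.75])

    def test_ties_get_average_ranks(self):
        assert np.allclose(cp.rank_transform([5.0, 5.0]), [0.5, 0.5])

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=40)
        assert np.array_equal(cp.rank_transform(x), cp.rank_transform(np.exp(x)))

    def test_rejects_short_sample(self):
        with pytest.raises(ValueError):
            cp.rank_transform([1.0])


class TestEmpiricalCopula:
    def test_single_pair(self):
        emp = cp.EmpiricalCopula([0.5], [0.5])
        assert emp(0.5, 0.5) == 1.0
        assert emp(0.4, 0.5) == 0.0

    def test_upper_corner_is_one(self, rng):
        emp = cp.EmpiricalCopula.from_data(rng.normal(size=20), rng.normal(size=20))
        assert emp(1.0, 1.0) == 1.0

    def test_comonotone_diagonal(self):
        x = np.arange(4.0)
        emp = cp.EmpiricalCopula.from_data(x, x)
        for k in range(1, 5):
            assert emp(k / 5.0, k / 5.0) == pytest.approx(k / 4.0)

    def test_matches_brute_force_for_small_samples(self, rng):
        for n in range(1, 13):
            u = rng.uniform(0.01, 0.99, n)
            v = rng.uniform(0.01, 0.99, n)
            emp = cp.EmpiricalCopula(u, v)
            for a, b in rng.uniform(0, 1, size=(10, 2)):
                assert emp(a, b) == pytest.approx(brute_force_empirical_copula(u, v, a, b))

    def test_monotone_invariance_of_sample(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        e1 = cp.EmpiricalCopula.from_data(x, y)
        e2 = cp.EmpiricalCopula.from_data(np.exp(x), y**3)
        grid = rng.uniform(0, 1, size=(15, 2))
        assert np.allclose(e1(grid[:, 0], grid[:, 1]), e2(grid[:, 0], grid[:, 1]))


class TestGenerator:
    def test_clayton_value(self):
        assert cp.generator("clayton", 1.0, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("family,theta", FAMILY_THETAS)
    def test_generator_vanishes_at_one_and_decreases(self, family, theta):
        gen = cp.make_copula(family, theta).generator
        assert gen(1.0) == pytest.approx(0.0, abs=1e-12)
        t = np.linspace(0.05, 1.0, 40)
        phi = gen(t)
        assert np.all(np.diff(phi) <= 1e-12)
        assert np.all(phi >= -1e-12)

    def test_rejects_theta_outside_domain(self):
        with pytest.raises(ValueError):
            cp.ClaytonCopula(-2.0)
        with pytest.raises(ValueError):
            cp.GumbelCopula(0.5)
        with pytest.raises(ValueError):
            cp.FrankCopula(np.inf)


class TestCopulaCdf:
    def test_clayton_closed_form_value(self):
        assert cp.make_copula("clayton", 2.0).cdf(0.5, 0.5) == pytest.approx(7.0**-0.5)

    def test_gumbel_theta_one_is_independence(self):
        c = cp.make_copula("gumbel", 1.0)
        assert c.cdf(0.3, 0.7) == pytest.approx(0.21)
        u = np.linspace(0.05, 0.95, 11)
        assert np.array_equal(c.cdf(u, u[::-1]), u * u[::-1])

    @pytest.mark.parametrize("family,theta", FAMILY_THETAS)
    def test_boundary_identities(self, family, theta, rng):
        c = cp.make_copula(family, theta)
        u = rng.uniform(0, 1, 1000)
        assert np.all(np.abs(c.cdf(u, np.zeros_like(u))) < 1e-12)
        assert np.all(np.abs(c.cdf(np.zeros_like(u), u)) < 1e-12)
        assert np.all(np.abs(c.cdf(u, np.ones_like(u)) - u) < 1e-9)
        assert np.all(np.abs(c.cdf(np.ones_like(u), u) - u) < 1e-9)
        assert c.cdf(0.42, 1.0) == pytest.approx(0.42, abs=1e-12)

    @pytest.mark.parametrize("family", ["clayton", "frank"])
    def test_independence_limit_small_theta(self, family, rng):
        c = cp.make_copula(family, 1e-6)
        u = rng.uniform(0.05, 0.95, 200)
        v = rng.uniform(0.05, 0.95, 200)
        assert np.max(np.abs(c.cdf(u, v) - u * v)) < 1e-4

    @pytest.mark.parametrize("family,theta", FAMILY_THETAS)
    def test_two_increasing(self, family, theta, rng):
        c = cp.make_copula(family, theta)
        for _ in range(200):
            u1, u2 = np.sort(rng.uniform(0, 1, 2))
            v1, v2 = np.sort(rng.uniform(0, 1, 2))
            vol = c.cdf(u2, v2) - c.cdf(u2, v1) - c.cdf(u1, v2) + c.cdf(u1, v1)
            assert vol >= -1e-12

    def test_rejects_arguments_outside_unit_square(self):
        with pytest.raises(ValueError):
            cp.make_copula("clayton", 2.0).cdf(1.2, 0.5)


class TestAgainstReferenceImplementation:
    """Cross-check cdf/pdf against statsmodels' copulas (independent oracle)."""

    @pytest.mark.parametrize(
        "family,theta", [("clayton", 2.0), ("frank", 5.0), ("frank", -3.0), ("gumbel", 2.5)]
    )
    def test_cdf_and_pdf_match(self, family, theta, rng):
        sm_api = pytest.importorskip("statsmodels.distributions.copula.api")
        ref_cls = {
            "clayton": sm_api.ClaytonCopula,
            "frank": sm_api.FrankCopula,
            "gumbel": sm_api.GumbelCopula,
        }[family]
        ref = ref_cls(theta)
        ours = cp.make_copula(family, theta)
        u = rng.uniform(0.05, 0.95, 300)
        v = rng.uniform(0.05, 0.95, 300)
        pts = np.column_stack([u, v])
        assert np.allclose(ours.cdf(u, v), ref.cdf(pts), atol=1e-12)
        assert np.allclose(ours.pdf(u, v), ref.pdf(pts), rtol=1e-9)


class TestConditionalCdf:
    def test_independence_returns_v(self, rng):
        c = cp.make_copula("gumbel", 1.0)
        v = rng.uniform(0.01, 0.99, 50)
        u = rng.uniform(0.01, 0.99, 50)
        assert np.allclose(c.conditional_cdf(v, u), v)

    def test_monotone_in_v(self):
        c = cp.make_copula("clayton", 2.0)
        grid = np.linspace(0.001, 0.999, 100)
        h = c.conditional_cdf(grid, 0.37)
        assert np.all(np.diff(h) >= 0.0)
        assert h[0] < 0.01 and h[-1] > 0.99

    @pytest.mark.parametrize("family,theta", FAMILY_THETAS)
    def test_matches_finite_difference_of_cdf(self, family, theta, rng):
        c = cp.make_copula(family, theta)
        eps = 1e-6
        for _ in range(20):
            u = rng.uniform(0.1, 0.9)
            v = rng.uniform(0.1, 0.9)
            fd = (c.cdf(u + eps, v) - c.cdf(u - eps, v)) / (2.0 * eps)
            assert c.conditional_cdf(v, u) == pytest.approx(fd, abs=1e-5)

    @pytest.mark.parametrize("family,theta", FAMILY_THETAS)
    def test_inverse_round_trip(self, family, theta, rng):
        c = cp.make_copula(family, theta)
        p = rng.uniform(0.01, 0.99, 200)
        u = rng.uniform(0.05, 0.95, 200)
        v = c.inverse_conditional_cdf(p, u)
        assert np.max(np.abs(c.conditional_cdf(v, u) - p)) < 1e-7


class TestConditionalSampling:
    def test_independence_samples_are_uniform(self):
        c = cp.make_copula("gumbel", 1.0)
        draws = c.conditional_sample(0.3, 3000, np.random.default_rng(7))
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_clayton_sample_median_matches_analytic(self):
        c = cp.make_copula("clayton", 8.0)
        draws = c.conditional_sample(0.5, 3000, np.random.default_rng(11))
        analytic = optimize.brentq(lambda v: c.conditional_cdf(v, 0.5) - 0.5, 1e-9, 1 - 1e-9)
        assert abs(np.median(draws) - analytic) < 0.05

    def test_same_seed_reproduces(self):
        c = cp.make_copula("frank", 4.0)
        a = cp.conditional_sample(c, 0.4, 100, seed=5)
        b = cp.conditional_sample(c, 0.4, 100, seed=5)
        assert np.array_equal(a, b)

    def test_rejects_bad_arguments(self):
        c = cp.make_copula("frank", 4.0)
        with pytest.raises(ValueError):
            c.conditional_sample(0.0, 10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            c.conditional_sample(0.5, 0, np.random.default_rng(0))


def simulate_pairs(family, theta, n, rng):
    """Draw dependent pairs by conditional inverse transform."""
    c = cp.make_copula(family, theta)
    u = rng.random(n)
    v = c.inverse_conditional_cdf(rng.random(n), u)
    return u, v


class TestFitML:
    def test_independent_sample_gumbel_near_one(self, rng):
        u, v = cp.pseudo_observations(rng.random(3000), rng.random(3000))
        assert abs(cp.fit_ml(u, v, "gumbel") - 1.0) < 0.05

    def test_independent_sample_frank_near_zero(self):
        # the Frank MLE at independence has sampling sd ~ 0.11 at n = 3000;
        # average a few seeded replicates so the band is a ~3 sigma test
        estimates = [
            cp.fit_ml(
                *cp.pseudo_observations(
                    np.random.default_rng(seed).random(3000),
                    np.random.default_rng(100 + seed).random(3000),
                ),
                "frank",
            )
            for seed in range(5)
        ]
        assert abs(np.mean(estimates)) < 0.15

    def test_clayton_parameter_recovery(self, rng):
        x, y = simulate_pairs("clayton", 2.0, 2000, rng)
        u, v = cp.pseudo_observations(x, y)
        assert 1.7 <= cp.fit_ml(u, v, "clayton") <= 2.3

    def test_estimate_stays_inside_domain(self, rng):
        # strongly negatively dependent sample: gumbel cannot go below 1
        x = rng.random(500)
        u, v = cp.pseudo_observations(x, -x + 0.01 * rng.random(500))
        assert cp.fit_ml(u, v, "gumbel") >= 1.0

    def test_rejects_small_sample(self, rng):
        u, v = cp.pseudo_observations(rng.random(5), rng.random(5))
        with pytest.raises(ValueError, match="at least 10"):
            cp.fit_ml(u, v, "clayton")


class TestGofSelect:
    def test_selected_family_attains_minimum_distance(self, rng):
        x, y = simulate_pairs("frank", 4.0, 400, rng)
        res = cp.gof_select(*cp.pseudo_observations(x, y))
        assert res.distances[res.family] == min(res.distances.values())
        assert res.theta == res.thetas[res.family]

    @pytest.mark.parametrize("family,theta", [("clayton", 3.0), ("gumbel", 3.0)])
    def test_generating_family_usually_selected(self, family, theta):
        picks = []
        for seed in range(8):
            rng = np.random.default_rng(1000 + seed)
            x, y = simulate_pairs(family, theta, 600, rng)
            picks.append(cp.gof_select(*cp.pseudo_observations(x, y)).family)
        assert picks.count(family) >= 6

    def test_rejects_small_sample(self, rng):
        u, v = cp.pseudo_observations(rng.random(20), rng.random(20))
        with pytest.raises(ValueError, match="at least 30"):
            cp.gof_select(u, v)
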