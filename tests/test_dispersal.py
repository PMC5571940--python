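import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import nbinom

from beetlekern.dispersal import (
    EXPONENTIAL,
    GAUSSIAN,
    DispersalParams,
    DomainError,
    ModelSpec,
    build_size_factor,
    cauchy_logpdf,
    delta_scale,
    expected_abundance,
    kernel_density,
    log_posterior,
    log_prior,
    mean_dispersal_distance,
    nb_loglik,
    parse_size_factor,
)
from beetlekern.landscape import SamplingPoint, WoodRaster


class TestDeltaScale:
    def test_constant_scale(self):
        assert delta_scale(DispersalParams(1.0, 0.0), 3) == 1.0

    def test_linear_growth(self):
        assert delta_scale(DispersalParams(0.5, 0.25), 3) == pytest.approx(1.0)

    def test_domain_violation_at_boundary(self):
        with pytest.raises(DomainError):
            delta_scale(DispersalParams(0.3, -0.1), 4)

    def test_negative_intercept_rejected(self):
        with pytest.raises(DomainError):
            delta_scale(DispersalParams(-0.1, 1.0), 1)

    def test_inverse_convention_is_reciprocal(self):
        p = DispersalParams(0.5, 0.25)
        assert delta_scale(p, 3, "inverse") == pytest.approx(1.0)
        assert delta_scale(p, 1, "inverse") == pytest.approx(2.0)


class TestKernels:
    def test_gaussian_density_at_origin(self):
        assert kernel_density(0.0, 1.0, GAUSSIAN) == pytest.approx(1 / math.pi)

    def test_exponential_density_at_origin(self):
        assert kernel_density(0.0, 1.0, EXPONENTIAL) == pytest.approx(
            1 / (2 * math.pi)
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(DomainError):
            kernel_density(1.0, 0.0, GAUSSIAN)

    @pytest.mark.parametrize("family", [GAUSSIAN, EXPONENTIAL])
    @pytest.mark.parametrize("delta", [0.5, 1.0, 2.0])
    def test_normalization_by_radial_quadrature(self, family, delta):
        mass, _ = quad(
            lambda r: kernel_density(r, delta, family) * 2 * math.pi * r, 0, np.inf
        )
        assert mass == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("family,expected", [
        (EXPONENTIAL, 2.0),
        (GAUSSIAN, math.sqrt(math.pi) / 2),
    ])
    def test_mean_distance_closed_forms(self, family, expected):
        got = mean_dispersal_distance(DispersalParams(1.0, 0.0), 1, family)
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize("family", [GAUSSIAN, EXPONENTIAL])
    def test_mean_distance_against_sampling_oracle(self, family, rng):
        # radial density: gaussian kernel -> Rayleigh(delta/sqrt(2));
        # exponential kernel -> Gamma(2, delta)
        delta, n = 1.7, 100_000
        if family is GAUSSIAN:
            draws = rng.rayleigh(delta / math.sqrt(2), size=n)
        else:
            draws = rng.gamma(2.0, delta, size=n)
        se = draws.std(ddof=1) / math.sqrt(n)
        closed = mean_dispersal_distance(DispersalParams(delta), 1, family)
        assert abs(draws.mean() - closed) < 3 * se


class TestNBLoglik:
    def test_zero_mean_zero_count_has_probability_one(self):
        assert nb_loglik(0, 0.0, 1.0) == 0.0

    def test_zero_mean_positive_count_impossible(self):
        assert nb_loglik(3, 0.0, 1.0) == -np.inf

    def test_poisson_limit(self):
        expect = math.log(math.exp(-2) * 2**3 / math.factorial(3))
        assert nb_loglik(3, 2.0, 1e6) == pytest.approx(expect, abs=1e-4)

    def test_normalization_by_direct_summation(self):
        k = np.arange(501)
        total = np.exp(nb_loglik(k, np.full_like(k, 5.0, dtype=float), 1.3)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_parameterization(self, rng):
        mus = rng.uniform(0.1, 30, 20)
        ks = rng.integers(0, 50, 20)
        theta = 1.7
        ours = nb_loglik(ks, mus, theta)
        ref = nbinom.logpmf(ks, theta, theta / (theta + mus))
        np.testing.assert_allclose(ours, ref, rtol=1e-10)


class TestPriors:
    def test_cauchy_at_center(self):
        assert cauchy_logpdf(0.0) == pytest.approx(math.log(1 / (2.5 * math.pi)))

    def test_two_coefficients_add(self):
        lp = log_prior(DispersalParams(1.0), [0.0, 0.0], 0.0)
        assert lp == pytest.approx(2 * math.log(1 / (2.5 * math.pi)))

    def test_negative_beta_d_outside_domain(self):
        assert log_prior(DispersalParams(-0.1), [0.0], 0.0) == -np.inf

    def test_decreasing_scale_leaving_domain(self):
        assert log_prior(DispersalParams(0.3, -0.1), [], 0.0) == -np.inf


class TestSizeFactors:
    def test_parse_accepts_both_term_orders(self):
        assert parse_size_factor("field+date") == ("+", ["field", "date"])
        assert parse_size_factor("date+field") == ("+", ["date", "field"])
        with pytest.raises(ValueError):
            parse_size_factor("weather")

    def test_additive_design_free_coefficient_count(self, small_table):
        d = build_size_factor("field+date", small_table)
        n_fields = small_table["field"].nunique()
        n_dates = small_table["date"].nunique()
        # all field levels free, first date level fixed to zero
        assert d.n_free == n_fields + n_dates - 1

    def test_interaction_design_one_per_observed_couple(self, small_table):
        d = build_size_factor("site:date", small_table)
        pairs = small_table.groupby(["site", "date"]).ngroups
        assert d.n_free == pairs

    def test_intercept_only(self, small_table):
        d = build_size_factor("1", small_table)
        assert d.n_free == 1
        np.testing.assert_allclose(d.X, 1.0)

    def test_unseen_level_rejected(self, small_table):
        d = build_size_factor("field", small_table.iloc[:20])
        alien = small_table.copy()
        alien["field"] = "nowhere"
        with pytest.raises(KeyError):
            d.linear_predictor(np.zeros(d.n_free), alien)


def _one_pixel_raster():
    # one full 100 m pixel (0.01 km2) centered at the origin cell
    return WoodRaster(100.0, [50.0], [50.0], [0.0], [10000.0])


class TestExpectedAbundance:
    def test_empty_sum_when_no_sources(self):
        spec = ModelSpec("date")
        raster = _one_pixel_raster()
        pt = SamplingPoint("p", "f", "s", 90000.0, 0.0)
        mu = expected_abundance(spec, DispersalParams(1.0), 0.0, pt, 1, raster)
        assert mu == 0.0

    def test_single_pixel_at_zero_distance(self):
        spec = ModelSpec("date", kernel="gaussian")
        raster = _one_pixel_raster()
        pt = SamplingPoint("p", "f", "s", 50.0, 50.0)
        mu = expected_abundance(spec, DispersalParams(1.0), 0.0, pt, 1, raster)
        assert mu == pytest.approx(0.01 / math.pi)

    def test_structure_none_ignores_geometry(self):
        spec = ModelSpec("date", point_structure="none")
        mu = expected_abundance(spec, None, math.log(15.2), None, 1, None)
        assert mu == pytest.approx(15.2)

    def test_strictly_decreasing_in_distance(self):
        raster = _one_pixel_raster()
        params = DispersalParams(1.0)
        for kernel in ("gaussian", "exponential"):
            spec = ModelSpec("date", kernel=kernel)
            mus = [
                expected_abundance(
                    spec, params, 0.0,
                    SamplingPoint("p", "f", "s", 50.0 + d, 50.0), 1, raster,
                )
                for d in (0.0, 200.0, 700.0, 2000.0, 4500.0)
            ]
            assert all(b < a for a, b in zip(mus, mus[1:]))


class TestLogPosterior:
    def _toy(self):
        table = pd.DataFrame(
            {
                "field": ["f1", "f1", "f2"],
                "site": ["s1", "s1", "s1"],
                "date": [1, 2, 1],
                "count": [2, 0, 5],
                "x": [150.0, 150.0, 400.0],
                "y": [50.0, 50.0, 50.0],
            }
        )
        return table, _one_pixel_raster()

    def test_empty_table_equals_prior(self):
        table, raster = self._toy()
        spec = ModelSpec("date")
        design = build_size_factor("date", table)
        lp = log_posterior(
            table.iloc[:0], raster, spec, DispersalParams(1.0), design,
            np.zeros(design.n_free), 0.0,
        )
        assert lp == pytest.approx(
            log_prior(DispersalParams(1.0), np.zeros(design.n_free), 0.0)
        )

    def test_hand_composed_single_observation(self):
        table, raster = self._toy()
        one = table.iloc[:1]
        spec = ModelSpec("date", kernel="gaussian")
        design = build_size_factor("date", one)
        coefs = np.array([0.3])
        params = DispersalParams(1.2, 0.0)
        pt = SamplingPoint("p", "f1", "s1", 150.0, 50.0)
        mu = expected_abundance(spec, params, 0.3, pt, 1, raster)
        expect = nb_loglik(2, mu, math.exp(0.1)) + log_prior(params, coefs, 0.1)
        got = log_posterior(one, raster, spec, params, design, coefs, 0.1)
        assert got == pytest.approx(expect)

    def test_invariant_to_observation_order(self):
        table, raster = self._toy()
        spec = ModelSpec("field+date", kernel="exponential")
        design = build_size_factor("field+date", table)
        coefs = np.array([0.5, -0.2, 0.8])
        args = (raster, spec, DispersalParams(0.8, 0.1), design, coefs, -0.3)
        fwd = log_posterior(table, *args)
        rev = log_posterior(table.iloc[::-1].reset_index(drop=True), *args)
        assert fwd == pytest.approx(rev)

    def test_merged_equals_split_when_points_at_barycenter(self):
        table, raster = self._toy()
        table = table.assign(x=[250.0, 250.0, 250.0], y=[80.0] * 3)
        design = build_size_factor("date", table)
        coefs = np.zeros(design.n_free)
        split = log_posterior(
            table, raster, ModelSpec("date", point_structure="split"),
            DispersalParams(1.0), design, coefs, 0.0,
        )
        merged = log_posterior(
            table, raster, ModelSpec("date", point_structure="merged"),
            DispersalParams(1.0), design, coefs, 0.0,
        )
        assert split == pytest.approx(merged)
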