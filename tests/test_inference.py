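import math

import numpy as np
import pytest
from scipy.stats import norm

from beetlekern._model import compile_model
from beetlekern.dispersal import ModelSpec, log_posterior
from beetlekern.inference import (
    Chain,
    ChainTooShortError,
    adaptive_metropolis,
    aic,
    credible_interval,
    fit_model,
    geweke_z,
    point_estimates,
    raftery_lewis,
    run_mcmc,
)


class TestGenericSampler:
    def test_standard_normal_target(self):
        samples, _, acc, _ = adaptive_metropolis(
            lambda x: -0.5 * float(x[0]) ** 2, [0.0], 50_000, seed=5
        )
        x = samples[5000:, 0]
        se = x.std(ddof=1) / math.sqrt(len(x) / 20)  # crude ESS deflation
        assert abs(x.mean()) < 3 * se
        assert abs(x.var() - 1.0) < 0.1

    def test_seeded_determinism(self):
        a, *_ = adaptive_metropolis(lambda x: -0.5 * x @ x, [0.0, 1.0], 500, seed=9)
        b, *_ = adaptive_metropolis(lambda x: -0.5 * x @ x, [0.0, 1.0], 500, seed=9)
        np.testing.assert_array_equal(a, b)


class TestGeweke:
    def test_iid_chain_passes(self, rng):
        z = geweke_z(rng.normal(size=10_000))
        assert abs(z) < 4

    def test_nominal_pass_rate_on_iid_chains(self, rng):
        passes = sum(
            abs(geweke_z(rng.normal(size=5000))) < 1.96 for _ in range(60)
        )
        assert passes >= 48  # ~nominal 95%, generous floor

    def test_constructed_drift_fails_loudly(self, rng):
        series = np.concatenate(
            [rng.normal(0, 1, 5000), rng.normal(5, 1, 5000)]
        )
        assert abs(geweke_z(series)) > 10

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            geweke_z(np.ones(1000))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.arange(50.0))


class TestRafteryLewis:
    def test_minimum_run_length_closed_form(self, rng):
        res = raftery_lewis(rng.normal(size=20_000))
        z = norm.ppf(0.975)
        assert res.n_min == math.ceil(z**2 * 0.025 * 0.975 / 0.005**2)
        assert res.n_min == 3746

    def test_iid_dependence_factor_near_one(self, rng):
        res = raftery_lewis(rng.normal(size=20_000))
        assert 0.8 <= res.dependence_factor <= 1.5

    def test_autocorrelation_inflates_dependence_factor(self, rng):
        iid = rng.normal(size=20_000)
        ar = np.empty(20_000)
        ar[0] = 0.0
        eps = rng.normal(size=20_000)
        for i in range(1, 20_000):
            ar[i] = 0.95 * ar[i - 1] + eps[i]
        assert (
            raftery_lewis(ar).dependence_factor
            > raftery_lewis(iid).dependence_factor
        )

    def test_too_short_series_reports_minimum(self, rng):
        with pytest.raises(ChainTooShortError) as err:
            raftery_lewis(rng.normal(size=100))
        assert err.value.n_min == 3746


class TestEstimates:
    def _chain(self, samples, lls):
        samples = np.asarray(samples, dtype=float)
        lls = np.asarray(lls, dtype=float)
        return Chain(
            samples=samples,
            log_likelihood=lls,
            log_posterior=lls,
            param_names=[f"p{i}" for i in range(samples.shape[1])],
            seed=0,
            acceptance_rates=np.zeros(samples.shape[1]),
            burn_in=0,
            converged=True,
            n_blocks=1,
        )

    def test_single_sample_chain(self):
        pe = point_estimates(self._chain([[1.0, 2.0]], [-3.0]))
        np.testing.assert_array_equal(pe.values, [1.0, 2.0])
        assert pe.method == "argmax"

    def test_bimodal_chain_prefers_argmax_over_median(self):
        # two modes at -1 and +1; the medians fall between the modes where
        # the likelihood is lowest, so the argmax sample must win
        samples = np.array([[-1.0], [-1.0], [1.0], [1.0], [0.9]])
        loglik = lambda v: -abs(abs(float(v[0])) - 1.0)
        lls = np.array([loglik(s) for s in samples])
        pe = point_estimates(self._chain(samples, lls), loglik=loglik)
        assert pe.method == "argmax"
        assert abs(pe.values[0]) == 1.0

    def test_median_wins_when_strictly_better(self):
        # the per-parameter median vector (0.5, 0) is not itself a sample
        # and beats every sampled point
        samples = np.array([[-2.0, 1.0], [0.5, -1.0], [2.0, 0.0]])
        loglik = lambda v: -float(v @ v)
        lls = np.array([loglik(s) for s in samples])
        pe = point_estimates(self._chain(samples, lls), loglik=loglik)
        assert pe.method == "median"
        np.testing.assert_allclose(pe.values, [0.5, 0.0])

    def test_credible_interval_type7(self):
        lo, hi = credible_interval(np.arange(1, 1001))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_credible_interval_constant_and_permutation(self, rng):
        assert credible_interval(np.full(10, 3.3)) == (3.3, 3.3)
        x = rng.normal(size=1000)
        assert credible_interval(x) == credible_interval(rng.permutation(x))

    def test_aic_arithmetic(self):
        assert aic(3, -10.0) == 26.0
        assert aic(5, -10.0) - aic(3, -10.0) == 4.0


@pytest.fixture(scope="module")
def fitted(small_study):
    spec = ModelSpec("date", kernel="gaussian")
    return fit_model(
        small_study.table, small_study.raster, spec,
        seed=31, block_size=600, max_blocks=2,
    )


class TestModelChains:
    def test_chain_shapes_and_finiteness(self, fitted):
        chain = fitted.chain
        assert chain.samples.shape == (1200, fitted.n_params)
        assert np.isfinite(chain.retained_loglik).all()
        assert fitted.aic == pytest.approx(
            2 * fitted.n_params - 2 * fitted.max_loglik
        )

    def test_same_seed_bit_identical(self, small_study):
        spec = ModelSpec("date", kernel="exponential")
        kw = dict(seed=77, block_size=300, max_blocks=2)
        a = run_mcmc(small_study.table, small_study.raster, spec, **kw)
        b = run_mcmc(small_study.table, small_study.raster, spec, **kw)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.log_likelihood, b.log_likelihood)

    def test_fast_loglik_matches_reference_model(self, small_study, rng):
        """The sampler's spline likelihood agrees with the plain
        numpy/scipy forward model across random parameter vectors."""
        spec = ModelSpec("site+date", kernel="gaussian")
        model = compile_model(small_study.table, small_study.raster, spec)
        for _ in range(5):
            vec = model.default_init()
            vec[0] = rng.uniform(0.3, 3.0)
            vec[1] = rng.uniform(-0.05, 0.3)
            vec[2:-1] = rng.normal(1.5, 1.0, model.n_coef)
            vec[-1] = rng.normal(0, 0.3)
            params, coefs, lt = model.unpack(vec)
            ref = log_posterior(
                small_study.table, small_study.raster, spec, params,
                model.design, coefs, lt,
            ) - model.log_prior(vec)
            assert model.loglik(vec) == pytest.approx(ref, abs=2e-4)

    def test_chain_loglik_matches_numpy_mirror(self, fitted):
        model = fitted.model
        chain = fitted.chain
        for i in (0, 300, 1199):
            assert chain.log_likelihood[i] == pytest.approx(
                model.loglik(chain.samples[i]), abs=1e-6
            )

    def test_init_outside_domain_rejected(self, small_study):
        spec = ModelSpec("date", kernel="gaussian")
        model = compile_model(small_study.table, small_study.raster, spec)
        bad = model.default_init()
        bad[0] = -1.0
        with pytest.raises(ValueError, match="domain"):
            run_mcmc(
                small_study.table, small_study.raster, spec,
                seed=1, init=bad, block_size=200, max_blocks=1, model=model,
            )

    def test_chain_persistence_roundtrip(self, fitted, tmp_path):
        csv = tmp_path / "chain.csv"
        fitted.chain.write(csv)
        import json

        import pandas as pd

        df = pd.read_csv(csv)
        assert list(df.columns[1:1 + fitted.n_params]) == fitted.chain.param_names
        meta = json.loads((tmp_path / "chain.csv.json").read_text())
        assert meta["seed"] == fitted.chain.seed
        assert meta["burn_in"] == fitted.chain.burn_in
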