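"""MCMC fitting, convergence diagnostics, point estimates and AIC.

The sampler is component-wise random-walk Metropolis with per-parameter
proposal scales adapted toward an acceptance rate of 0.44 during the
first block (the burn-in), then frozen.  Sampling proceeds in blocks
until the Geweke stationarity diagnostic and the Raftery-Lewis run-length
diagnostic are satisfied on the post-burn-in chain for every parameter,
or a block budget is exhausted (the chain is then flagged, not rejected,
so model sweeps always complete).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._mcmc_core import run_chain
from ._model import CompiledModel, compile_model
from .dispersal import ModelSpec, mean_dispersal_distance
from .landscape import CUTOFF_DEFAULT, WoodRaster

GEWEKE_THRESHOLD = 1.96


class ChainTooShortError(ValueError):
    """Series shorter than the Raftery-Lewis minimum; carries ``n_min``."""

    def __init__(self, n: int, n_min: int):
        super().__init__(
            f"series of length {n} is shorter than the Raftery-Lewis "
            f"minimum N_min = {n_min}"
        )
        self.n_min = n_min


# ---------------------------------------------------------------------------
# diagnostics


def _spectral_variance_of_mean(x: np.ndarray) -> float:
    """Variance of the sample mean with a Bartlett-window (Newey-West)
    estimate of the spectral density at frequency zero."""
    n = len(x)
    xc = x - x.mean()
    L = min(n - 1, int(4 * (n / 100.0) ** (2.0 / 9.0)))
    s = float(xc @ xc) / n
    for lag in range(1, L + 1):
        gamma = float(xc[lag:] @ xc[:-lag]) / n
        s += 2.0 * (1.0 - lag / (L + 1.0)) * gamma
    return max(s, 1e-300) / n


def geweke_z(series, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke stationarity z-score comparing the means of the first 10%
    and last 50% of the chain (spectral variance estimates)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("Geweke diagnostic needs at least 100 draws")
    if not 0 < first < 1 or not 0 < last < 1 or first + last > 1:
        raise ValueError("invalid window fractions")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant series: Geweke diagnostic undefined")
    va = _spectral_variance_of_mean(a)
    vb = _spectral_variance_of_mean(b)
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))


@dataclass(frozen=True)
class RafteryLewisResult:
    burn_in: int
    required_n: int
    dependence_factor: float
    thin: int
    n_min: int


def _markov_bic(z: np.ndarray) -> float:
    """BIC contrast of a second-order vs first-order two-state Markov fit."""
    tri = np.zeros((2, 2, 2))
    for a, b, c in zip(z[:-2], z[1:-1], z[2:]):
        tri[a, b, c] += 1
    n = tri.sum()
    ll2 = 0.0
    for a in range(2):
        for b in range(2):
            rs = tri[a, b].sum()
            for c in range(2):
                if tri[a, b, c] > 0:
                    ll2 += tri[a, b, c] * math.log(tri[a, b, c] / rs)
    pair = tri.sum(axis=0)
    ll1 = 0.0
    for b in range(2):
        rs = pair[b].sum()
        for c in range(2):
            if pair[b, c] > 0:
                ll1 += pair[b, c] * math.log(pair[b, c] / rs)
    g2 = 2.0 * (ll2 - ll1)
    return g2 - 2.0 * math.log(n)


def raftery_lewis(
    series,
    q: float = 0.025,
    r: float = 0.005,
    s: float = 0.95,
    eps: float = 0.001,
) -> RafteryLewisResult:
    """Raftery-Lewis run-length diagnostic for estimating the q-quantile
    to within +/- r with probability s.

    Implements the two-state Markov chain construction on the indicator
    of lying below the empirical q-quantile, with thinning chosen by a
    BIC contrast of second- vs first-order dependence.
    """
    x = np.asarray(series, dtype=float)
    z975 = float(norm.ppf((s + 1) / 2))
    n_min = math.ceil(z975**2 * q * (1 - q) / r**2)
    if len(x) < n_min:
        raise ChainTooShortError(len(x), n_min)
    u = np.quantile(x, q)
    zbin = (x <= u).astype(np.int64)
    thin = 1
    while True:
        zt = zbin[::thin]
        if len(zt) < 16 or _markov_bic(zt) <= 0:
            break
        thin += 1
    zt = zbin[::thin]
    trans = np.zeros((2, 2))
    for a, b in zip(zt[:-1], zt[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1)
    alpha = trans[0, 1] / row[0] if row[0] > 0 else 0.5
    beta = trans[1, 0] / row[1] if row[1] > 0 else 0.5
    alpha = min(max(alpha, 1e-8), 1 - 1e-8)
    beta = min(max(beta, 1e-8), 1 - 1e-8)
    lam = 1.0 - alpha - beta
    if abs(lam) < 1e-12:
        burn = thin
    else:
        burn = thin * math.ceil(
            math.log(eps * (alpha + beta) / max(alpha, beta)) / math.log(abs(lam))
        )
        burn = max(burn, 0)
    post = thin * math.ceil(
        (2.0 - alpha - beta) * alpha * beta / (alpha + beta) ** 3 * (z975 / r) ** 2
    )
    total = int(burn + post)
    return RafteryLewisResult(
        burn_in=int(burn),
        required_n=total,
        dependence_factor=total / n_min,
        thin=thin,
        n_min=n_min,
    )


# ---------------------------------------------------------------------------
# generic adaptive Metropolis (arbitrary log-posterior callables)


def adaptive_metropolis(
    logpost,
    init,
    n_iter: int,
    seed: int,
    scales=None,
    adapt: bool = True,
    target_accept: float = 0.44,
    adapt_window: int = 50,
    adapt_step: float = 0.8,
):
    """Component-wise adaptive random-walk Metropolis for an arbitrary
    log-posterior callable.  Returns (samples, logpost values, acceptance
    rates, final scales)."""
    rng = np.random.default_rng(seed)
    x = np.array(init, dtype=float)
    d = x.size
    scales = np.ones(d) if scales is None else np.array(scales, dtype=float)
    lp = float(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("init has non-finite log posterior")
    samples = np.empty((n_iter, d))
    lps = np.empty(n_iter)
    acc = np.zeros(d)
    acc_win = np.zeros(d)
    for it in range(n_iter):
        for j in range(d):
            prop = x.copy()
            prop[j] += scales[j] * rng.normal()
            lp_new = float(logpost(prop))
            if math.log(rng.random()) < lp_new - lp:
                x = prop
                lp = lp_new
                acc[j] += 1
                acc_win[j] += 1
        if adapt and (it + 1) % adapt_window == 0:
            rates = acc_win / adapt_window
            scales *= np.exp(adapt_step * (rates - target_accept))
            np.clip(scales, 1e-8, 1e6, out=scales)
            acc_win[:] = 0
        samples[it] = x
        lps[it] = lp
    return samples, lps, acc / n_iter, scales


# ---------------------------------------------------------------------------
# model chains


@dataclass
class Chain:
    """MCMC output: all iterations (burn-in included) plus bookkeeping."""

    samples: np.ndarray
    log_likelihood: np.ndarray
    log_posterior: np.ndarray
    param_names: list[str]
    seed: int
    acceptance_rates: np.ndarray
    burn_in: int
    converged: bool
    n_blocks: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def retained(self) -> np.ndarray:
        return self.samples[self.burn_in:]

    @property
    def retained_loglik(self) -> np.ndarray:
        return self.log_likelihood[self.burn_in:]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.param_names)
        df.insert(0, "iteration", np.arange(len(df)))
        df["log_likelihood"] = self.log_likelihood
        df["log_posterior"] = self.log_posterior
        return df

    def write(self, csv_path, json_path=None) -> None:
        """Persist samples as CSV plus a JSON sidecar of metadata."""
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "seed": int(self.seed),
            "param_names": self.param_names,
            "burn_in": int(self.burn_in),
            "converged": bool(self.converged),
            "n_blocks": int(self.n_blocks),
            "acceptance_rates": [float(a) for a in self.acceptance_rates],
            "diagnostics": _jsonable(self.diagnostics),
        }
        if json_path is None:
            json_path = str(csv_path) + ".json"
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _check_convergence(retained: np.ndarray, threshold: float, rl_kwargs: dict):
    """Geweke + Raftery-Lewis on every parameter of the retained chain."""
    zs, rls = [], []
    ok = True
    for j in range(retained.shape[1]):
        col = retained[:, j]
        try:
            z = geweke_z(col)
        except ValueError:
            z = math.inf
        zs.append(z)
        if not abs(z) < threshold:
            ok = False
        try:
            rl = raftery_lewis(col, **rl_kwargs)
        except ChainTooShortError as err:
            rls.append({"required_n": err.n_min, "dependence_factor": math.nan})
            ok = False
            continue
        rls.append(
            {
                "required_n": rl.required_n,
                "dependence_factor": rl.dependence_factor,
                "thin": rl.thin,
            }
        )
        if len(col) < rl.required_n:
            ok = False
    return ok, zs, rls


def run_mcmc(
    table,
    raster: WoodRaster | None,
    spec: ModelSpec,
    *,
    seed: int,
    init=None,
    block_size: int = 5000,
    max_blocks: int = 40,
    cutoff: float = CUTOFF_DEFAULT,
    target_accept: float = 0.44,
    adapt_window: int = 50,
    adapt_step: float = 0.8,
    geweke_threshold: float = GEWEKE_THRESHOLD,
    rl_kwargs: dict | None = None,
    model: CompiledModel | None = None,
) -> Chain:
    """Fit one model spec by blockwise adaptive Metropolis.

    The first block is the burn-in (proposal adaptation enabled, then
    frozen); after each further block the Geweke and Raftery-Lewis
    diagnostics are evaluated on the post-burn-in chain, and sampling
    stops when both pass for every parameter or ``max_blocks`` blocks
    have been drawn (flagged non-converged).  Identical seed and inputs
    give identical chains.
    """
    if model is None:
        model = compile_model(table, raster, spec, cutoff=cutoff)
    x = model.default_init() if init is None else np.array(init, dtype=float)
    if len(x) != model.n_params:
        raise ValueError(
            f"init has length {len(x)}, model has {model.n_params} parameters"
        )
    if not model.in_domain(x):
        raise ValueError("init is outside the prior definition domain")
    rl_kwargs = {} if rl_kwargs is None else dict(rl_kwargs)
    d = model.n_params
    scales = np.full(d, 0.5)
    block_seeds = np.random.SeedSequence(seed).generate_state(max_blocks) % (2**31)
    all_samples, all_ll, all_lp = [], [], []
    acc = np.zeros(d, dtype=np.int64)
    inv = model.spec.delta_convention == "inverse"
    converged = False
    diagnostics: dict = {}
    n_blocks = 0
    for b in range(max_blocks):
        samples = np.empty((block_size, d))
        ll_out = np.empty(block_size)
        lp_out = np.empty(block_size)
        run_chain(
            int(block_seeds[b]), block_size, b == 0, target_accept,
            adapt_window, adapt_step,
            x, scales,
            model.k, model.active,
            model.col_indptr, model.col_rows,
            model.n_beta, model.T, inv,
            model.obs_point, model.obs_date, model.point_group,
            model.has_source,
            model.sp_x0, model.sp_h, model.sp_c,
            model.sp_ylo, model.sp_yhi, model.sp_slo, model.sp_shi,
            2.5,
            samples, ll_out, lp_out, acc,
        )
        all_samples.append(samples)
        all_ll.append(ll_out)
        all_lp.append(lp_out)
        n_blocks = b + 1
        if b >= 1:
            retained = np.concatenate(all_samples[1:])
            ok, zs, rls = _check_convergence(retained, geweke_threshold, rl_kwargs)
            diagnostics = {"geweke_z": zs, "raftery_lewis": rls}
            if ok:
                converged = True
                break
    total = np.concatenate(all_samples)
    return Chain(
        samples=total,
        log_likelihood=np.concatenate(all_ll),
        log_posterior=np.concatenate(all_lp),
        param_names=list(model.param_names),
        seed=seed,
        acceptance_rates=acc / (len(total)),
        burn_in=block_size,
        converged=converged,
        n_blocks=n_blocks,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# estimates, intervals, AIC


@dataclass(frozen=True)
class PointEstimates:
    values: np.ndarray
    method: str  # "argmax" or "median"
    log_likelihood: float


def point_estimates(chain: Chain, loglik=None) -> PointEstimates:
    """Point estimates from a chain.

    Returns the sample maximizing the likelihood within the chain, unless
    the vector of per-parameter medians achieves a strictly higher
    likelihood (evaluated with ``loglik``), in which case the median
    vector is returned and the choice recorded.
    """
    retained = chain.retained
    lls = chain.retained_loglik
    if len(retained) == 0:
        retained, lls = chain.samples, chain.log_likelihood
    if len(retained) == 0:
        raise ValueError("empty chain")
    i_best = int(np.argmax(lls))
    best, ll_best = retained[i_best].copy(), float(lls[i_best])
    if loglik is not None:
        med = np.median(retained, axis=0)
        ll_med = float(loglik(med))
        if ll_med > ll_best:
            return PointEstimates(med, "median", ll_med)
    return PointEstimates(best, "argmax", ll_best)


def credible_interval(series, lo: float = 0.025, hi: float = 0.975):
    """Empirical central credible interval (linear-interpolation
    quantiles)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.quantile(x, lo)), float(np.quantile(x, hi))


def aic(n_params: int, max_loglik: float) -> float:
    """Akaike information criterion 2k - 2 log L_max."""
    return 2.0 * n_params - 2.0 * max_loglik


@dataclass
class FitResult:
    """A fitted model: chain, per-parameter estimates with 95% intervals,
    and AIC from the chain's maximum likelihood."""

    spec: ModelSpec
    chain: Chain
    model: CompiledModel
    estimates: pd.DataFrame
    method: str
    max_loglik: float
    n_params: int
    converged: bool

    @property
    def aic(self) -> float:
        return aic(self.n_params, self.max_loglik)

    def params_by_group(self):
        return self.model.unpack(self.estimates["value"].to_numpy())

    def mean_dmean(self) -> float:
        """Mean dispersal distance averaged over observed dates (and over
        sites for site-dependent dispersal), km, at the point estimates."""
        params, _, _ = self.params_by_group()
        if params is None:
            return math.nan
        groups = params.values() if isinstance(params, dict) else [params]
        vals = [
            mean_dispersal_distance(
                p, t, self.spec.kernel, self.spec.delta_convention
            )
            for p in groups
            for t in range(1, self.model.T + 1)
        ]
        return float(np.mean(vals))


def fit_model(
    table,
    raster: WoodRaster | None,
    spec: ModelSpec,
    *,
    seed: int,
    **mcmc_kwargs,
) -> FitResult:
    """Compile, sample and summarize one model spec."""
    model = mcmc_kwargs.pop("model", None)
    if model is None:
        cutoff = mcmc_kwargs.get("cutoff", CUTOFF_DEFAULT)
        model = compile_model(table, raster, spec, cutoff=cutoff)
    chain = run_mcmc(table, raster, spec, seed=seed, model=model, **mcmc_kwargs)
    pe = point_estimates(chain, loglik=model.loglik)
    retained = chain.retained
    rows = []
    for j, name in enumerate(chain.param_names):
        lo, hi = credible_interval(retained[:, j])
        rows.append({"parameter": name, "value": pe.values[j], "lo": lo, "hi": hi})
    est = pd.DataFrame(rows).set_index("parameter")
    return FitResult(
        spec=spec,
        chain=chain,
        model=model,
        estimates=est,
        method=pe.method,
        max_loglik=pe.log_likelihood,
        n_params=model.n_params,
        converged=chain.converged,
    )
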