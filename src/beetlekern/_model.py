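"""Array compilation of a model specification for fast posterior evaluation.

The sampler evaluates the likelihood hundreds of thousands of times, so
the per-point kernel sum

    S_u(delta) = sum_w A_w * exp(-(d_uw / delta)^n) / (K * pi * delta^2)

is precomputed on a log-spaced grid of delta and interpolated by a cubic
spline of log S against log delta during sampling (linear continuation
beyond the grid, where log S is asymptotically linear in log delta).  The
readable exact path lives in :mod:`beetlekern.dispersal`; tests compare
the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

from . import dispersal as disp
from .io import validate_abundance
from .landscape import CUTOFF_DEFAULT, WoodRaster, source_distances

DELTA_GRID_RANGE = (0.02, 60.0)  # km; spans the posterior-relevant scales
DELTA_GRID_KNOTS = 160


@dataclass
class CompiledModel:
    """A model spec bound to data, ready for the sampler.

    Parameter vector layout: [beta_d per group..., beta_dt per group...,
    size-factor coefficients..., log_theta].  ``beta_groups`` is
    ``["global"]`` or the sorted site labels for site-dependent dispersal;
    structure "none" has no beta block.
    """

    spec: disp.ModelSpec
    design: disp.SizeFactorDesign
    table: pd.DataFrame
    param_names: list[str]
    beta_groups: list[str]
    n_beta: int
    T: int
    dates: list[int]
    k: np.ndarray
    active: np.ndarray
    col_indptr: np.ndarray
    col_rows: np.ndarray
    obs_point: np.ndarray
    obs_date: np.ndarray
    point_group: np.ndarray
    has_source: np.ndarray
    sp_x0: float
    sp_h: float
    sp_c: np.ndarray
    sp_ylo: np.ndarray
    sp_yhi: np.ndarray
    sp_slo: np.ndarray
    sp_shi: np.ndarray
    cutoff: float = CUTOFF_DEFAULT

    # ---- layout helpers ---------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_coef(self) -> int:
        return self.n_params - 2 * self.n_beta - 1

    @property
    def n_obs(self) -> int:
        return len(self.k)

    def default_init(self) -> np.ndarray:
        x = np.zeros(self.n_params)
        x[: self.n_beta] = 1.0  # beta_d = 1 km
        return x

    def unpack(self, vec: np.ndarray):
        vec = np.asarray(vec, dtype=float)
        nb = self.n_beta
        coefs = vec[2 * nb : self.n_params - 1]
        log_theta = float(vec[-1])
        if nb == 0:
            return None, coefs, log_theta
        params = {
            g: disp.DispersalParams(float(vec[i]), float(vec[nb + i]))
            for i, g in enumerate(self.beta_groups)
        }
        if not self.spec.site_dependent:
            params = params["global"]
        return params, coefs, log_theta

    def in_domain(self, vec: np.ndarray) -> bool:
        nb = self.n_beta
        for g in range(nb):
            bd, bdt = vec[g], vec[nb + g]
            if bd <= 0 or bd + bdt * (self.T - 1) <= 0:
                return False
        return True

    # ---- evaluation (numpy mirror of the sampler's arithmetic) ------------
    def _logS_matrix(self, bd: np.ndarray, bdt: np.ndarray) -> np.ndarray:
        U = len(self.has_source)
        out = np.full((U, self.T), -np.inf)
        nseg = self.sp_c.shape[1]
        xe = self.sp_x0 + nseg * self.sp_h
        inv = self.spec.delta_convention == "inverse"
        for g in range(self.n_beta):
            sel = (self.point_group == g) & self.has_source
            for t in range(self.T):
                lin = bd[g] + bdt[g] * t
                delta = 1.0 / lin if inv else lin
                lx = math.log(delta)
                if lx <= self.sp_x0:
                    y = self.sp_ylo[sel] + self.sp_slo[sel] * (lx - self.sp_x0)
                elif lx >= xe:
                    y = self.sp_yhi[sel] + self.sp_shi[sel] * (lx - xe)
                else:
                    idx = min(int((lx - self.sp_x0) / self.sp_h), nseg - 1)
                    dx = lx - (self.sp_x0 + idx * self.sp_h)
                    c = self.sp_c[sel, idx, :]
                    y = ((c[:, 0] * dx + c[:, 1]) * dx + c[:, 2]) * dx + c[:, 3]
                out[sel, t] = y
        return out

    def linear_predictor(self, coefs: np.ndarray) -> np.ndarray:
        return self.design.X @ np.asarray(coefs, dtype=float)

    def loglik(self, vec: np.ndarray) -> float:
        """Log likelihood at a parameter vector, on the same (spline)
        surface the sampler uses."""
        vec = np.asarray(vec, dtype=float)
        if not self.in_domain(vec):
            return -np.inf
        nb = self.n_beta
        coefs = vec[2 * nb : -1]
        theta = math.exp(float(vec[-1]))
        m = self.linear_predictor(coefs)
        if nb > 0:
            logS = self._logS_matrix(vec[:nb], vec[nb : 2 * nb])
            m = m + logS[self.obs_point, self.obs_date]
        a = self.active
        ka = self.k[a].astype(float)
        ma = m[a]
        mu = np.exp(ma)
        lden = np.log(theta + mu)
        from scipy.special import gammaln

        csum = float(
            np.sum(gammaln(ka + theta) - gammaln(theta) - gammaln(ka + 1))
        )
        return csum + float(
            np.sum(theta * (math.log(theta) - lden) + ka * (ma - lden))
        )

    def log_prior(self, vec: np.ndarray) -> float:
        if not self.in_domain(vec):
            return -np.inf
        coefs = vec[2 * self.n_beta : -1]
        return float(np.sum(disp.cauchy_logpdf(coefs)))

    def log_posterior(self, vec: np.ndarray) -> float:
        lp = self.log_prior(vec)
        if not np.isfinite(lp):
            return lp
        return lp + self.loglik(vec)


def compile_model(
    table: pd.DataFrame,
    raster: WoodRaster | None,
    spec: disp.ModelSpec,
    cutoff: float = CUTOFF_DEFAULT,
    n_knots: int = DELTA_GRID_KNOTS,
    delta_range: tuple[float, float] = DELTA_GRID_RANGE,
) -> CompiledModel:
    """Bind a model spec to data, building the sampler's arrays."""
    df = validate_abundance(table)
    n = len(df)
    if n == 0:
        raise ValueError("empty abundance table")
    design = disp.build_size_factor(spec.size_factor, df)
    k = df["count"].to_numpy(dtype=np.int64)
    dates = sorted(int(d) for d in df["date"].unique())
    T = len(dates)
    date_idx = {d: i for i, d in enumerate(dates)}
    obs_date = np.asarray([date_idx[int(d)] for d in df["date"]], dtype=np.int64)

    # size-factor columns -> observation rows (CSR by column)
    p = design.n_free
    rows_per_col: list[list[int]] = [[] for _ in range(p)]
    X = design.X
    for i in range(n):
        for j in np.nonzero(X[i])[0]:
            rows_per_col[j].append(i)
    col_indptr = np.zeros(p + 1, dtype=np.int64)
    for j in range(p):
        col_indptr[j + 1] = col_indptr[j] + len(rows_per_col[j])
    col_rows = np.asarray(
        [i for rows in rows_per_col for i in rows], dtype=np.int64
    )

    fam = disp.kernel_family(spec.kernel) if spec.has_kernel else None
    if spec.has_kernel:
        if raster is None:
            raise ValueError("split/merged structures require a woodland raster")
        points = disp.prepare_points(df, spec.point_structure)
        keys = {}
        obs_point = np.zeros(n, dtype=np.int64)
        uniq = []
        for i, pt in enumerate(points):
            key = (pt.site_id, pt.field_id, pt.x, pt.y)
            if key not in keys:
                keys[key] = len(uniq)
                uniq.append(pt)
            obs_point[i] = keys[key]
        U = len(uniq)
        sites = sorted(df["site"].astype(str).unique())
        if spec.site_dependent:
            beta_groups = sites
            group_of_site = {s: g for g, s in enumerate(sites)}
            point_group = np.asarray(
                [group_of_site[pt.site_id] for pt in uniq], dtype=np.int64
            )
        else:
            beta_groups = ["global"]
            point_group = np.zeros(U, dtype=np.int64)
        n_beta = len(beta_groups)

        lo, hi = delta_range
        xgrid = np.linspace(math.log(lo), math.log(hi), n_knots)
        deltas = np.exp(xgrid)
        Y = np.zeros((n_knots, U))
        has_source = np.zeros(U, dtype=bool)
        for u, pt in enumerate(uniq):
            src = source_distances(pt, raster, cutoff=cutoff, origin=spec.origin)
            if len(src.distance) == 0:
                continue
            has_source[u] = True
            d_km = src.distance / 1000.0
            a_km2 = src.area / 1e6
            # log-stable: log S = logsumexp(log a - (d/delta)^n) - log(K pi delta^2)
            W = np.log(a_km2)[None, :] - (d_km[None, :] / deltas[:, None]) ** fam.n
            Y[:, u] = logsumexp(W, axis=1) - np.log(fam.K * math.pi * deltas**2)
        bad = ~has_source[obs_point] & (k > 0)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} observations have positive counts but no "
                f"woodland source within {cutoff} m; the model assigns them "
                "probability zero"
            )
        active = np.nonzero(has_source[obs_point])[0].astype(np.int64)
        cs = CubicSpline(xgrid, Y, axis=0)
        sp_c = np.ascontiguousarray(np.transpose(cs.c, (2, 1, 0)))
        dcs = cs.derivative()
        sp_slo = np.asarray(dcs(xgrid[0]), dtype=float)
        sp_shi = np.asarray(dcs(xgrid[-1]), dtype=float)
        sp_ylo = Y[0].copy()
        sp_yhi = Y[-1].copy()
        sp_x0 = float(xgrid[0])
        sp_h = float(xgrid[1] - xgrid[0])
    else:
        obs_point = np.zeros(n, dtype=np.int64)
        point_group = np.zeros(1, dtype=np.int64)
        has_source = np.zeros(1, dtype=bool)
        beta_groups = []
        n_beta = 0
        active = np.arange(n, dtype=np.int64)
        sp_c = np.zeros((1, 1, 4))
        sp_slo = sp_shi = sp_ylo = sp_yhi = np.zeros(1)
        sp_x0, sp_h = 0.0, 1.0

    names = (
        [f"beta_d[{g}]" if n_beta > 1 else "beta_d" for g in beta_groups]
        + [f"beta_dt[{g}]" if n_beta > 1 else "beta_dt" for g in beta_groups]
        + [f"coef[{lab}]" for lab in design.levels]
        + ["log_theta"]
    )
    return CompiledModel(
        spec=spec,
        design=design,
        table=df,
        param_names=names,
        beta_groups=beta_groups,
        n_beta=n_beta,
        T=T,
        dates=dates,
        k=k,
        active=active,
        col_indptr=col_indptr,
        col_rows=col_rows,
        obs_point=obs_point,
        obs_date=obs_date,
        point_group=point_group,
        has_source=has_source,
        sp_x0=sp_x0,
        sp_h=sp_h,
        sp_c=sp_c,
        sp_ylo=sp_ylo,
        sp_yhi=sp_yhi,
        sp_slo=sp_slo,
        sp_shi=sp_shi,
        cutoff=cutoff,
    )
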