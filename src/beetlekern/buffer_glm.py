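"""Baseline buffer-area regression and radius scan.

The baseline relates counts to the woodland area A_BW inside a disk
around each sampling point:

    log mu(t, i) = beta_G(level) + log A_BW

a negative-binomial GLM with canonical log link and log(A_BW) as an
offset with fixed unit coefficient.  The size theta is profiled: for
fixed theta the coefficient fit is an IRLS GLM (statsmodels), and theta
is maximized by bounded scalar search.  The buffer radius is chosen by
scanning 0.2-5 km in 200 m steps and taking the best likelihood (ties
toward the smallest radius).

Observations with A_BW = 0 enter through the exact mu -> 0 limit: they
contribute log-probability 0 when the count is 0 and -inf otherwise (no
epsilon floor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .dispersal import build_size_factor, nb_loglik
from .io import validate_abundance
from .landscape import SamplingPoint, WoodRaster, buffer_wood_area

DEFAULT_RADII_KM = np.round(np.arange(0.2, 5.0 + 1e-9, 0.2), 10)


@dataclass
class BufferFit:
    radius_km: float
    size_factor: str
    levels: list[str]
    coef: np.ndarray  # one beta_G per level, log scale; NaN if unsupported
    theta: float
    max_loglik: float
    n_params: int
    n_zero_area: int
    impossible: bool  # a positive count had zero buffer area


@dataclass
class BufferScan:
    best_radius_km: float
    best_fit: BufferFit
    profile: pd.DataFrame


def buffer_areas(table: pd.DataFrame, raster: WoodRaster, radius_km: float,
                 origin: str = "area") -> np.ndarray:
    """Woodland area (km2) in a disk of ``radius_km`` around each
    observation's sampling point."""
    df = validate_abundance(table)
    cache: dict[tuple, float] = {}
    out = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        key = (row.x, row.y)
        if key not in cache:
            pt = SamplingPoint("p", str(row.field), str(row.site), row.x, row.y)
            cache[key] = buffer_wood_area(pt, raster, radius_km * 1000.0, origin)
        out[i] = cache[key] / 1e6
    return out


def _profile_loglik(k, X, offset, log_theta, start=None):
    """Max log likelihood over coefficients at fixed theta (IRLS)."""
    theta = math.exp(log_theta)
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(k, X, family=fam, offset=offset).fit(
                start_params=start, maxiter=200, tol=1e-10
            )
    except (ValueError, np.linalg.LinAlgError):
        # IRLS can fail at extreme theta during profiling
        return -1e12, start
    mu = res.mu
    ll = float(np.sum(nb_loglik(k, mu, theta)))
    return ll, np.asarray(res.params)


def fit_buffer_model(
    table: pd.DataFrame,
    raster: WoodRaster,
    radius_km: float,
    size_factor: str = "site:date",
    origin: str = "area",
    areas: np.ndarray | None = None,
) -> BufferFit:
    """Fit the buffer GLM at one radius, profiling theta."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    df = validate_abundance(table)
    if areas is None:
        areas = buffer_areas(df, raster, radius_km, origin)
    areas = np.asarray(areas, dtype=float)
    k = df["count"].to_numpy()
    pos = areas > 0
    if not pos.any():
        raise ValueError("every observation has zero woodland area in the buffer")
    impossible = bool(((~pos) & (k > 0)).any())
    design = build_size_factor(size_factor, df)
    X_full = design.X
    supported = X_full[pos].sum(axis=0) > 0
    X = X_full[np.ix_(pos, supported)]
    kp = k[pos]
    off = np.log(areas[pos])

    if kp.sum() == 0:
        # all in-buffer counts are zero: the supremum is the mu -> 0 limit
        coef = np.full(design.n_free, np.nan)
        return BufferFit(
            radius_km=float(radius_km),
            size_factor=size_factor,
            levels=list(design.levels),
            coef=coef,
            theta=1.0,
            max_loglik=-math.inf if impossible else 0.0,
            n_params=int(supported.sum()) + 1,
            n_zero_area=int((~pos).sum()),
            impossible=impossible,
        )

    state = {"params": None}

    def neg_profile(lt):
        ll, params = _profile_loglik(kp, X, off, lt, start=state["params"])
        state["params"] = params
        return -ll

    opt = minimize_scalar(
        neg_profile, bounds=(-8.0, 10.0), method="bounded",
        options={"xatol": 1e-7},
    )
    log_theta = float(opt.x)
    ll, params = _profile_loglik(kp, X, off, log_theta, start=state["params"])
    if params is None or ll <= -1e11:
        raise ValueError("buffer GLM did not converge at the profiled theta")
    coef = np.full(design.n_free, np.nan)
    coef[supported] = params
    max_ll = -math.inf if impossible else ll  # zero-area/count-0 rows add 0
    return BufferFit(
        radius_km=float(radius_km),
        size_factor=size_factor,
        levels=list(design.levels),
        coef=coef,
        theta=math.exp(log_theta),
        max_loglik=max_ll,
        n_params=int(supported.sum()) + 1,
        n_zero_area=int((~pos).sum()),
        impossible=impossible,
    )


def scan_buffer_radius(
    table: pd.DataFrame,
    raster: WoodRaster,
    size_factor: str = "site:date",
    radii=None,
    origin: str = "area",
) -> BufferScan:
    """Profile the buffer fit over a radius grid; best = maximum
    likelihood, ties broken toward the smallest radius."""
    radii = DEFAULT_RADII_KM if radii is None else np.asarray(radii, dtype=float)
    if len(radii) == 0:
        raise ValueError("empty radius grid")
    df = validate_abundance(table)
    rows = []
    best = None
    for radius in radii:
        fit = fit_buffer_model(df, raster, radius, size_factor, origin)
        rows.append(
            {
                "radius_km": fit.radius_km,
                "max_loglik": fit.max_loglik,
                "theta": fit.theta,
                "n_zero_area": fit.n_zero_area,
            }
        )
        if best is None or fit.max_loglik > best.max_loglik:
            best = fit
    profile = pd.DataFrame(rows)
    return BufferScan(
        best_radius_km=best.radius_km, best_fit=best, profile=profile
    )
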