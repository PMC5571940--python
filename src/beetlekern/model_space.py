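"""Factorial modality space: enumeration, batch fitting, AIC ranking.

The modality grid crosses the size-factor structure, the source origin
(whole woodland area vs 100 m edge band), the point structure (split /
merged / none), the kernel family and site-dependent dispersal.  Under
the "none" structure the geometry modalities are meaningless, so the
cross product collapses to a single spec per size factor there.  The full
default grid therefore enumerates 8*2*2*2*2 + 8 = 136 distinct models.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .dispersal import ORIGINS, SIZE_FACTOR_STRUCTURES, ModelSpec
from .inference import FitResult, credible_interval, fit_model

SPEC_COLUMNS = ["size_factor", "origin", "point_structure", "kernel", "site_dependent"]


@dataclass(frozen=True)
class ModalityGrid:
    size_factors: tuple = SIZE_FACTOR_STRUCTURES
    origins: tuple = ORIGINS
    structures: tuple = ("split", "merged", "none")
    kernels: tuple = ("gaussian", "exponential")
    site_dependent: tuple = (False, True)
    delta_convention: str = "scale"

    def __post_init__(self):
        for name in ("size_factors", "origins", "structures", "kernels", "site_dependent"):
            if not getattr(self, name):
                raise ValueError(f"grid subset {name} must be non-empty")


def enumerate_models(grid: ModalityGrid | None = None) -> list[ModelSpec]:
    """Cross product of the grid modalities with the "none" collapse rule
    applied; duplicates removed, order deterministic."""
    grid = grid or ModalityGrid()
    specs: list[ModelSpec] = []
    seen = set()
    for sf in grid.size_factors:
        for structure in grid.structures:
            if structure == "none":
                candidates = [
                    ModelSpec(
                        size_factor=sf,
                        point_structure="none",
                        delta_convention=grid.delta_convention,
                    )
                ]
            else:
                candidates = [
                    ModelSpec(
                        size_factor=sf,
                        origin=origin,
                        point_structure=structure,
                        kernel=kernel,
                        site_dependent=sd,
                        delta_convention=grid.delta_convention,
                    )
                    for origin in grid.origins
                    for kernel in grid.kernels
                    for sd in grid.site_dependent
                ]
            for spec in candidates:
                if spec.label not in seen:
                    seen.add(spec.label)
                    specs.append(spec)
    return specs


def spec_seed(master_seed: int, spec: ModelSpec) -> int:
    """Deterministic per-spec sub-seed (stable across orderings and
    duplicate lists)."""
    digest = hashlib.sha256(f"{master_seed}|{spec.label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RankingTable:
    """AIC ranking of fitted specs, best first."""

    table: pd.DataFrame
    fits: dict = dc_field(default_factory=dict)

    def best(self) -> pd.Series:
        return self.table.iloc[0]


def _dmean_interval(fit: FitResult):
    """Per-iteration mean dispersal distance (over groups and dates),
    95% interval from the retained chain."""
    model = fit.model
    nb = model.n_beta
    if nb == 0:
        return math.nan, math.nan, math.nan, math.nan
    retained = fit.chain.retained
    bd = retained[:, :nb]
    bdt = retained[:, nb : 2 * nb]
    t = np.arange(model.T)
    lin = bd[:, :, None] + bdt[:, :, None] * t[None, None, :]
    if fit.spec.delta_convention == "inverse":
        delta = 1.0 / lin
    else:
        delta = lin
    factor = 2.0 if fit.spec.kernel == "exponential" else math.sqrt(math.pi) / 2.0
    dmean_iter = factor * delta.mean(axis=(1, 2))
    bdt_iter = bdt.mean(axis=1)
    d_lo, d_hi = credible_interval(dmean_iter)
    b_lo, b_hi = credible_interval(bdt_iter)
    return d_lo, d_hi, b_lo, b_hi


def _fit_row(fit: FitResult) -> dict:
    row = fit.spec.to_dict()
    row.update(
        n_params=fit.n_params,
        max_loglik=fit.max_loglik,
        aic=fit.aic,
        converged=fit.converged,
        estimate_method=fit.method,
    )
    params, _, _ = fit.params_by_group()
    if params is None:
        row.update(
            mean_beta_dt=math.nan, beta_dt_lo=math.nan, beta_dt_hi=math.nan,
            mean_dmean=math.nan, dmean_lo=math.nan, dmean_hi=math.nan,
        )
    else:
        groups = params.values() if isinstance(params, dict) else [params]
        row["mean_beta_dt"] = float(np.mean([p.beta_dt for p in groups]))
        row["mean_dmean"] = fit.mean_dmean()
        d_lo, d_hi, b_lo, b_hi = _dmean_interval(fit)
        row.update(dmean_lo=d_lo, dmean_hi=d_hi, beta_dt_lo=b_lo, beta_dt_hi=b_hi)
    return row


def fit_all(
    specs,
    table,
    raster,
    *,
    seed: int,
    progress: bool = False,
    **mcmc_kwargs,
) -> RankingTable:
    """Fit every spec with an independent, spec-derived sub-seed and rank
    by AIC.  Individual failures (e.g. non-identifiable data for a spec)
    become flagged rows, not exceptions."""
    rows = []
    fits: dict[str, FitResult] = {}
    for i, spec in enumerate(specs):
        if progress:
            print(f"[{i + 1}/{len(specs)}] {spec.label}")
        sub = spec_seed(seed, spec)
        try:
            fit = fit_model(table, raster, spec, seed=sub, **mcmc_kwargs)
        except ValueError as err:
            row = spec.to_dict()
            row.update(
                n_params=np.nan, max_loglik=np.nan, aic=np.nan, converged=False,
                estimate_method="failed", error=str(err),
            )
            rows.append(row)
            continue
        fits[spec.label] = fit
        rows.append(_fit_row(fit))
    df = pd.DataFrame(rows)
    df = df.sort_values("aic", kind="stable", na_position="last").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return RankingTable(table=df, fits=fits)


def constrain_and_best(
    ranking: RankingTable | pd.DataFrame,
    allow_field_effect: bool = True,
    **constraints,
) -> pd.Series:
    """Best (minimum AIC) row subject to modality constraints, optionally
    excluding size factors with a field term."""
    df = ranking.table if isinstance(ranking, RankingTable) else ranking
    mask = np.ones(len(df), dtype=bool)
    for key, value in constraints.items():
        if key not in df.columns:
            raise KeyError(f"unknown modality {key!r}")
        col = df[key]
        mask &= (col == value) | (col.isna() & pd.isna(value))
    if not allow_field_effect:
        mask &= ~df["size_factor"].str.contains("field")
    sub = df[mask & df["aic"].notna()]
    if sub.empty:
        raise ValueError(f"no fitted model matches constraints {constraints}")
    return sub.loc[sub["aic"].idxmin()]
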