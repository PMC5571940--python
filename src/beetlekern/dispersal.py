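"""Forward model: dispersal kernels, expected abundance, likelihood, priors.

Expected abundance at sampling point *i* and date *t* is

    mu(t, i) = gamma_g * sum_w gamma_d(d_iw, delta(t)) * A_w

where the sum runs over woodland source pixels w within 5 km, A_w is the
pixel's wooded area, gamma_d is a two-dimensional dispersal kernel
(gaussian or exponential) with a distance scale delta(t) that changes
linearly with the weekly date index, and gamma_g = exp(coef) is a
categorical size factor (date/field/site designs) absorbing detectability
and emergence intensity.  Counts are negative binomial with mean mu and
size theta (variance mu + mu^2/theta).

Internal computations use km and km2; coordinates and areas arrive in
meters from the landscape module and are converted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .landscape import (
    CUTOFF_DEFAULT,
    SamplingPoint,
    WoodRaster,
    merge_field_points,
    source_distances,
)

COEF_PRIOR_SCALE = 2.5  # Cauchy prior scale for log size-factor coefficients

SIZE_FACTOR_STRUCTURES = (
    "1",
    "date",
    "field",
    "site",
    "field+date",
    "site+date",
    "field:date",
    "site:date",
)

POINT_STRUCTURES = ("split", "merged", "none")
ORIGINS = ("area", "edge")
DELTA_CONVENTIONS = ("scale", "inverse")


def parse_size_factor(structure: str):
    """Parse a size-factor structure string.

    Returns (operator, terms): operator "" (single term or "1"), "+"
    (additive) or ":" (interaction).  Terms come from {date, field,
    site}; any order is accepted ("field+date" == "date+field" as a
    model, though coefficients are labelled per the given string).
    """
    s = structure.strip()
    if s == "1":
        return "", ["1"]
    for op in ("+", ":"):
        if op in s:
            terms = [t.strip() for t in s.split(op)]
            if len(terms) != 2 or len(set(terms)) != 2 or not all(
                t in ("date", "field", "site") for t in terms
            ):
                raise ValueError(f"invalid size factor structure {structure!r}")
            return op, terms
    if s not in ("date", "field", "site"):
        raise ValueError(f"unknown size factor structure {structure!r}")
    return "", [s]


class DomainError(ValueError):
    """A parameter left its definition domain (e.g. delta(t) <= 0)."""


@dataclass(frozen=True)
class KernelFamily:
    """Two-dimensional dispersal kernel family.

    Density at distance d for scale delta:
        gamma_d = 1 / (K * pi * delta^2) * exp(-(d / delta)^n)
    gaussian: (K, n) = (1, 2); exponential: (K, n) = (2, 1).  Both
    integrate to one over the plane.
    """

    name: str
    K: float
    n: float


GAUSSIAN = KernelFamily("gaussian", 1.0, 2.0)
EXPONENTIAL = KernelFamily("exponential", 2.0, 1.0)
_FAMILIES = {"gaussian": GAUSSIAN, "exponential": EXPONENTIAL}


def kernel_family(family) -> KernelFamily:
    if isinstance(family, KernelFamily):
        return family
    try:
        return _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown kernel family {family!r}") from None


@dataclass(frozen=True)
class DispersalParams:
    """Distance-scale parameters (km): intercept ``beta_d`` at the first
    date and weekly linear change ``beta_dt``."""

    beta_d: float
    beta_dt: float = 0.0


def delta_scale(
    params: DispersalParams,
    t: int,
    convention: str = "scale",
) -> float:
    """Kernel distance scale delta(t), km, at weekly date index t >= 1.

    Canonical convention ("scale"): delta(t) = beta_d + beta_dt * (t - 1).
    The alternative "inverse" convention reads the linear form as the
    reciprocal scale: delta(t) = 1 / (beta_d + beta_dt * (t - 1)).
    """
    if convention not in DELTA_CONVENTIONS:
        raise ValueError(f"unknown delta convention {convention!r}")
    if t < 1 or int(t) != t:
        raise ValueError("date index t must be an integer >= 1")
    lin = params.beta_d + params.beta_dt * (t - 1)
    if params.beta_d <= 0 or lin <= 0:
        raise DomainError(
            f"delta(t) domain violation: beta_d={params.beta_d}, "
            f"beta_d + beta_dt*(t-1)={lin} at t={t}"
        )
    return lin if convention == "scale" else 1.0 / lin


def kernel_density(d, delta: float, family) -> np.ndarray | float:
    """Planar kernel density (per km2) at distance d (km)."""
    fam = kernel_family(family)
    if delta <= 0:
        raise DomainError("kernel scale delta must be positive")
    d = np.asarray(d, dtype=float)
    out = np.exp(-((d / delta) ** fam.n)) / (fam.K * math.pi * delta**2)
    return out if out.ndim else float(out)


def mean_dispersal_distance(
    params: DispersalParams,
    t: int,
    family,
    convention: str = "scale",
) -> float:
    """Mean radial dispersal distance D_mean(t), km.

    exponential: 2 * delta(t);  gaussian: sqrt(pi)/2 * delta(t).
    """
    fam = kernel_family(family)
    delta = delta_scale(params, t, convention)
    if fam.name == "exponential":
        return 2.0 * delta
    return math.sqrt(math.pi) / 2.0 * delta


@dataclass(frozen=True)
class ModelSpec:
    """One point in the factorial modality space.

    When ``point_structure`` is "none" the geometry-related modalities
    (origin, kernel, site-dependent dispersal) are meaningless and are
    normalized to ``None`` so equal specs compare equal.
    """

    size_factor: str
    origin: str | None = "area"
    point_structure: str = "split"
    kernel: str | None = "gaussian"
    site_dependent: bool | None = False
    delta_convention: str = "scale"

    def __post_init__(self) -> None:
        parse_size_factor(self.size_factor)
        if self.point_structure not in POINT_STRUCTURES:
            raise ValueError(f"unknown point structure {self.point_structure!r}")
        if self.delta_convention not in DELTA_CONVENTIONS:
            raise ValueError(f"unknown delta convention {self.delta_convention!r}")
        if self.point_structure == "none":
            object.__setattr__(self, "origin", None)
            object.__setattr__(self, "kernel", None)
            object.__setattr__(self, "site_dependent", None)
        else:
            if self.origin not in ORIGINS:
                raise ValueError(f"unknown origin {self.origin!r}")
            kernel_family(self.kernel)
            object.__setattr__(self, "site_dependent", bool(self.site_dependent))

    @property
    def has_kernel(self) -> bool:
        return self.point_structure != "none"

    @property
    def label(self) -> str:
        return (
            f"{self.size_factor}|{self.origin}|{self.point_structure}|"
            f"{self.kernel}|{self.site_dependent}|{self.delta_convention}"
        )

    def to_dict(self) -> dict:
        return {
            "size_factor": self.size_factor,
            "origin": self.origin,
            "point_structure": self.point_structure,
            "kernel": self.kernel,
            "site_dependent": self.site_dependent,
            "delta_convention": self.delta_convention,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# size factor designs


def _term_labels(term: str, row) -> str:
    return f"{term}={row[term]}"


@dataclass
class SizeFactorDesign:
    """Categorical size-factor design on the log scale.

    ``levels`` names one free coefficient each.  For additive designs
    ("a+b") all levels of the first factor are free and the first level of
    each further factor is fixed to zero so the overall amplitude is
    carried once.  Interaction designs ("a:b") have one free coefficient
    per observed couple; "1" a single coefficient.
    """

    structure: str
    levels: list[str] = field(default_factory=list)
    X: np.ndarray | None = None  # n x p indicator matrix for the build table

    def __post_init__(self) -> None:
        self._zeroed: list[str] = []

    @property
    def n_free(self) -> int:
        return len(self.levels)

    def column_indices(self, table: pd.DataFrame) -> list[np.ndarray]:
        """Column index list per row of ``table`` (raises on unseen levels)."""
        lookup = {lab: j for j, lab in enumerate(self.levels)}
        zero_ok = set(self._zeroed)
        rows = []
        for _, row in table.iterrows():
            cols = []
            for lab in self._row_labels(row):
                if lab in lookup:
                    cols.append(lookup[lab])
                elif lab not in zero_ok:
                    raise KeyError(f"level {lab!r} not in size-factor design")
            rows.append(np.asarray(cols, dtype=np.int64))
        return rows

    def linear_predictor(self, coefs: np.ndarray, table: pd.DataFrame) -> np.ndarray:
        coefs = np.asarray(coefs, dtype=float)
        if len(coefs) != self.n_free:
            raise ValueError(
                f"expected {self.n_free} coefficients, got {len(coefs)}"
            )
        eta = np.zeros(len(table))
        for i, cols in enumerate(self.column_indices(table)):
            eta[i] = coefs[cols].sum()
        return eta

    # internal -------------------------------------------------------------
    def _row_labels(self, row) -> list[str]:
        s = self.structure
        if s == "1":
            return ["1"]
        if ":" in s:
            a, b = s.split(":")
            return [f"{a}={row[a]}:{b}={row[b]}"]
        if "+" in s:
            return [_term_labels(term, row) for term in s.split("+")]
        return [_term_labels(s, row)]


def build_size_factor(structure: str, table: pd.DataFrame) -> SizeFactorDesign:
    """Build the size-factor design implied by the data's label sets."""
    parse_size_factor(structure)
    design = SizeFactorDesign(structure=structure)
    levels: list[str] = []
    zeroed: list[str] = []
    if structure == "1":
        levels = ["1"]
    elif ":" in structure:
        a, b = structure.split(":")
        pairs = sorted(
            {(str(r[a]), str(r[b])) for _, r in table.iterrows()}
        )
        levels = [f"{a}={u}:{b}={v}" for u, v in pairs]
    else:
        terms = structure.split("+")
        for pos, term in enumerate(terms):
            vals = sorted(map(str, table[term].unique()))
            labs = [f"{term}={v}" for v in vals]
            if pos == 0:
                levels.extend(labs)
            else:
                zeroed.append(labs[0])  # reference level of later factors
                levels.extend(labs[1:])
    design.levels = levels
    design._zeroed = zeroed
    lookup = {lab: j for j, lab in enumerate(levels)}
    X = np.zeros((len(table), len(levels)))
    for i, (_, row) in enumerate(table.iterrows()):
        for lab in design._row_labels(row):
            if lab in lookup:
                X[i, lookup[lab]] = 1.0
    design.X = X
    return design


# ---------------------------------------------------------------------------
# expected abundance and likelihood


def expected_abundance(
    spec: ModelSpec,
    params: DispersalParams,
    log_size: float,
    point: SamplingPoint | None,
    t: int,
    raster: WoodRaster | None,
    cutoff: float = CUTOFF_DEFAULT,
) -> float:
    """Expected count mu(t, i) for one observation.

    ``log_size`` is the observation's size-factor linear predictor (log
    scale).  For merged structures the caller supplies the field
    barycenter as the point; for structure "none" geometry is ignored and
    mu = exp(log_size).
    """
    if not spec.has_kernel:
        return math.exp(log_size)
    if point is None or raster is None:
        raise ValueError("split/merged structures need a point and a raster")
    src = source_distances(point, raster, cutoff=cutoff, origin=spec.origin)
    if len(src.distance) == 0:
        return 0.0
    delta = delta_scale(params, t, spec.delta_convention)
    d_km = src.distance / 1000.0
    a_km2 = src.area / 1e6
    dens = kernel_density(d_km, delta, spec.kernel)
    return math.exp(log_size) * float(np.sum(dens * a_km2))


def nb_loglik(count, mu, theta: float):
    """Negative-binomial log density with mean mu and size theta.

    Variance is mu + mu^2/theta.  mu = 0 is the point mass at zero
    (continuity limit): log-probability 0 for count 0, -inf otherwise.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    k = np.asarray(count, dtype=float)
    m = np.asarray(mu, dtype=float)
    if (k < 0).any() or not np.allclose(k, np.round(k)):
        raise ValueError("counts must be non-negative integers")
    if (m < 0).any():
        raise ValueError("mu must be non-negative")
    scalar = k.ndim == 0 and m.ndim == 0
    k, m = np.broadcast_arrays(k, m)
    out = np.full(k.shape, -np.inf, dtype=float)
    zero = m == 0
    out[zero & (k == 0)] = 0.0
    pos = ~zero
    kp, mp = k[pos], m[pos]
    out[pos] = (
        gammaln(kp + theta)
        - gammaln(theta)
        - gammaln(kp + 1)
        + theta * np.log(theta / (theta + mp))
        + kp * np.log(mp / (theta + mp))
    )
    return float(out) if scalar else out


def cauchy_logpdf(x, scale: float = COEF_PRIOR_SCALE):
    x = np.asarray(x, dtype=float)
    out = -np.log(math.pi * scale) - np.log1p((x / scale) ** 2)
    return float(out) if out.ndim == 0 else out


def log_prior(
    params_by_group,
    coefs,
    log_theta: float,
    dates=(1, 2, 3, 4),
    spec: ModelSpec | None = None,
) -> float:
    """Joint log prior.

    Size-factor coefficients: independent Cauchy(0, 2.5) on the log scale.
    log(theta): flat.  Dispersal parameters: flat on their definition
    domain (beta_d > 0 and delta(t) > 0 at every observed date), -inf
    outside.  ``params_by_group`` is a DispersalParams, a mapping of them
    (site-dependent dispersal), or None (structure "none").
    """
    del log_theta  # flat prior
    lp = float(np.sum(cauchy_logpdf(np.asarray(coefs, dtype=float))))
    convention = spec.delta_convention if spec is not None else "scale"
    if params_by_group is None:
        return lp
    groups = (
        params_by_group.values()
        if isinstance(params_by_group, Mapping)
        else [params_by_group]
    )
    for p in groups:
        try:
            for t in dates:
                delta_scale(p, t, convention)
        except DomainError:
            return -math.inf
    return lp


def prepare_points(table: pd.DataFrame, point_structure: str):
    """Per-row SamplingPoint under a point structure (None for "none").

    "split" uses the actual coordinates; "merged" replaces each field's
    points by the field barycenter.
    """
    if point_structure == "none":
        return [None] * len(table)
    pts = [
        SamplingPoint(
            point_id=f"r{i}",
            field_id=str(row["field"]),
            site_id=str(row["site"]),
            x=float(row["x"]),
            y=float(row["y"]),
        )
        for i, (_, row) in enumerate(table.iterrows())
    ]
    if point_structure == "split":
        return pts
    if point_structure != "merged":
        raise ValueError(f"unknown point structure {point_structure!r}")
    by_field: dict[str, SamplingPoint] = {}
    for fid in table["field"].unique():
        members = {
            (p.x, p.y): p for p in pts if p.field_id == str(fid)
        }
        by_field[str(fid)] = merge_field_points(list(members.values()))
    return [by_field[p.field_id] for p in pts]


def log_posterior(
    table: pd.DataFrame,
    raster: WoodRaster | None,
    spec: ModelSpec,
    params_by_group,
    design: SizeFactorDesign,
    coefs,
    log_theta: float,
    cutoff: float = CUTOFF_DEFAULT,
) -> float:
    """Reference (readable, unoptimized) log posterior of the full model.

    Sums the negative-binomial log likelihood over observations and adds
    the joint log prior.  This is the plain numpy/scipy path used to
    validate the optimized sampler.
    """
    dates = tuple(sorted(table["date"].unique())) if len(table) else (1,)
    lp = log_prior(params_by_group, coefs, log_theta, dates=dates, spec=spec)
    if not np.isfinite(lp):
        return lp
    if len(table) == 0:
        return lp
    eta = design.linear_predictor(np.asarray(coefs, dtype=float), table)
    points = prepare_points(table, spec.point_structure)
    theta = math.exp(log_theta)
    total = lp
    for i, (_, row) in enumerate(table.iterrows()):
        if spec.has_kernel:
            if isinstance(params_by_group, Mapping):
                p = params_by_group[str(row["site"])]
            else:
                p = params_by_group
        else:
            p = None
        mu = expected_abundance(
            spec, p, eta[i], points[i], int(row["date"]), raster, cutoff=cutoff
        )
        total += nb_loglik(int(row["count"]), mu, theta)
        if not np.isfinite(total):
            return -math.inf
    return total
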