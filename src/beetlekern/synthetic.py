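"""Synthetic landscapes and abundance tables.

The generator emulates the study design the analysis assumes: a handful
of agricultural sites of a few km each with clustered woodland patches of
differing total cover, crop fields sampled along 5-point transects 50 m
apart running from the field edge (nearest the woods) toward the field
middle, observed on consecutive weekly dates.  Counts are negative
binomial around kernel-driven means, so every stage of the analysis can
be exercised and calibrated without any external data.

All randomness flows from one master seed through named numpy
sub-streams; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import nearest_points, unary_union

from . import dispersal as disp
from .io import read_abundance, write_abundance
from .landscape import (
    CUTOFF_DEFAULT,
    EDGE_BAND_DEFAULT,
    RESOLUTION_DEFAULT,
    SamplingPoint,
    WoodRaster,
    classify_edge_core,
)

# site woodland cover fractions mirroring a simple-to-complex gradient
DEFAULT_COVER = (0.142, 0.238, 0.291, 0.331)
SITE_NAMES_4 = ("HS", "S", "C", "HC")

# s2 I/O (canonical CSV dialect with published-header aliases)
read_s2_format = read_abundance
write_s2_format = write_abundance


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: sites, fields, transect points, weekly dates."""

    n_sites: int = 4
    fields_per_site: int | tuple = 6
    points_per_field: int = 5
    point_spacing: float = 50.0  # m
    n_dates: int = 4
    site_extent: tuple = (4000.0, 6000.0)  # m
    wood_cover: float | tuple = DEFAULT_COVER
    site_spacing: float = 30000.0  # m between site origins (x axis)
    wood_patch_scale: float = 1000.0  # median patch width, m
    resolution: float = RESOLUTION_DEFAULT
    edge_band: float = EDGE_BAND_DEFAULT

    def __post_init__(self):
        if self.n_sites < 1 or self.points_per_field < 1 or self.n_dates < 1:
            raise ValueError("counts must be positive")
        if self.point_spacing <= 0:
            raise ValueError("point spacing must be positive")
        for c in self.cover_by_site():
            if not 0 < c <= 0.5:
                raise ValueError("woodland cover fraction must be in (0, 0.5]")

    def site_names(self) -> list[str]:
        if self.n_sites == 4:
            return list(SITE_NAMES_4)
        return [f"S{i + 1}" for i in range(self.n_sites)]

    def fields_by_site(self) -> list[int]:
        f = self.fields_per_site
        if isinstance(f, int):
            return [f] * self.n_sites
        if len(f) != self.n_sites:
            raise ValueError("fields_per_site tuple must match n_sites")
        return [int(v) for v in f]

    def cover_by_site(self) -> list[float]:
        c = self.wood_cover
        if isinstance(c, (int, float)):
            return [float(c)] * self.n_sites
        out = [float(c[i % len(c)]) for i in range(self.n_sites)]
        return out

    def site_origin(self, s: int) -> tuple[float, float]:
        return (s * self.site_spacing, 0.0)


@dataclass(frozen=True)
class GeneratingTruth:
    """Ground truth for recovery studies: kernel, dispersal scale,
    size-factor coefficients (log scale) and NB size theta."""

    params: disp.DispersalParams | Mapping
    kernel: str = "gaussian"
    theta: float = 1.0
    origin: str = "area"
    size_factor: str = "date"
    coef: Mapping = field(default_factory=dict)
    delta_convention: str = "scale"

    def spec(self, point_structure: str = "split") -> disp.ModelSpec:
        return disp.ModelSpec(
            size_factor=self.size_factor,
            origin=self.origin,
            point_structure=point_structure,
            kernel=self.kernel,
            site_dependent=isinstance(self.params, Mapping),
            delta_convention=self.delta_convention,
        )

    def log_size(self, row) -> float:
        s = self.size_factor
        if s == "1":
            labels = ["1"]
        elif ":" in s:
            a, b = s.split(":")
            labels = [f"{a}={row[a]}:{b}={row[b]}"]
        else:
            labels = [f"{t}={row[t]}" for t in s.split("+")]
        try:
            return float(sum(self.coef[lab] for lab in labels))
        except KeyError as err:
            raise KeyError(f"truth lacks coefficient for level {err}") from None

    def params_for_site(self, site: str) -> disp.DispersalParams:
        if isinstance(self.params, Mapping):
            return self.params[site]
        return self.params

    def validate(self, n_dates: int) -> None:
        groups = (
            self.params.values()
            if isinstance(self.params, Mapping)
            else [self.params]
        )
        for p in groups:
            for t in range(1, n_dates + 1):
                disp.delta_scale(p, t, self.delta_convention)
        if self.theta <= 0:
            raise ValueError("theta must be positive")


# date effects spanning the observed dynamic range: a rainy-week dip at
# t2 and a flowering peak at t3
DATE_OFFSETS = (0.0, -0.8, 2.0, 1.2)


def baseline_truth(base: float = 2.5) -> GeneratingTruth:
    """Default truth preset: gaussian kernel with beta_d = 1.35 km and no
    time trend (mean dispersal distance ~1.2 km), theta = 1, date-level
    size factors."""
    coef = {f"date={t + 1}": base + DATE_OFFSETS[t % 4] for t in range(4)}
    return GeneratingTruth(
        params=disp.DispersalParams(beta_d=1.35, beta_dt=0.0),
        kernel="gaussian",
        theta=1.0,
        size_factor="date",
        coef=coef,
    )


def field_effect_truth(
    field_labels,
    seed: int,
    base: float = 3.2,
    beta_d: float = 0.35,
    beta_dt: float = 0.1,
    theta: float = 5.0,
    field_sd: float = 0.6,
    n_dates: int = 4,
) -> GeneratingTruth:
    """Truth with separate field and date effects and a short dispersal
    scale that widens week by week, so both the within-field transect
    gradient and the distance-by-date interaction are informative."""
    rng = np.random.default_rng(seed)
    coef = {f"date={t + 1}": base + DATE_OFFSETS[t % 4] for t in range(n_dates)}
    for lab in field_labels:
        coef[f"field={lab}"] = float(rng.normal(0.0, field_sd))
    return GeneratingTruth(
        params=disp.DispersalParams(beta_d=beta_d, beta_dt=beta_dt),
        kernel="gaussian",
        theta=theta,
        size_factor="field+date",
        coef=coef,
    )


# ---------------------------------------------------------------------------
# landscape


def simulate_landscape(design: StudyDesign, seed: int, max_attempts: int = 200):
    """Seeded woodland landscape: rectangular patches per site until each
    site's cover fraction is within 10% of its target.

    Returns ``(polygons, raster)`` — the vector patches and their
    edge/core rasterization.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    polygons = []
    covers = design.cover_by_site()
    ex, ey = design.site_extent
    for s in range(design.n_sites):
        ox, oy = design.site_origin(s)
        target = covers[s] * ex * ey
        for _ in range(max_attempts):
            patches = []
            area = 0.0
            while area < target and len(patches) < 500:
                ps = design.wood_patch_scale
                w = float(np.clip(rng.lognormal(math.log(ps), 0.45), 150, ex / 2))
                h = float(np.clip(rng.lognormal(math.log(0.7 * ps), 0.45), 150, ey / 2))
                remaining = target - area
                if w * h > remaining * 1.1:
                    f = math.sqrt(max(remaining, 0.02 * target) / (w * h))
                    w, h = max(w * f, 80.0), max(h * f, 80.0)
                cx = rng.uniform(ox + w / 2, ox + ex - w / 2)
                cy = rng.uniform(oy + h / 2, oy + ey - h / 2)
                patches.append(box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
                area = unary_union(patches).area
            if abs(area - target) / target <= 0.10:
                polygons.extend(patches)
                break
        else:
            raise RuntimeError(
                f"could not reach woodland cover {covers[s]:.2f} for site {s}"
            )
    raster = classify_edge_core(
        polygons, band=design.edge_band, resolution=design.resolution
    )
    return polygons, raster


# distance-to-wood bands (m) cycled over a site's fields so sampled
# fields span the abundance gradient, as transect-based designs do
FIELD_DISTANCE_BANDS = ((150.0, 800.0), (800.0, 1800.0), (1800.0, math.inf))


def simulate_fields(design: StudyDesign, polygons, seed: int,
                    max_attempts: int = 4000) -> pd.DataFrame:
    """Place fields and their 5-point transects.

    Field centers fall outside the woodlands, stratified over
    distance-to-wood bands so each site samples the whole gradient; the
    transect runs away from the nearest woodland edge, its first point on
    the woodland-facing side of the field.  Returns one row per sampling
    point with columns field, site, x, y.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    woods = unary_union(polygons)
    ex, ey = design.site_extent
    margin = 300.0
    half = (design.points_per_field - 1) / 2.0
    rows = []
    for s, site in enumerate(design.site_names()):
        ox, oy = design.site_origin(s)
        centers: list[tuple[float, float]] = []
        n_fields = design.fields_by_site()[s]
        for f in range(n_fields):
            lo_d, hi_d = FIELD_DISTANCE_BANDS[f % len(FIELD_DISTANCE_BANDS)]
            for attempt in range(max_attempts):
                if attempt == max_attempts // 2:
                    lo_d, hi_d = 150.0, math.inf  # band unreachable: relax
                cx = rng.uniform(ox + margin, ox + ex - margin)
                cy = rng.uniform(oy + margin, oy + ey - margin)
                c = Point(cx, cy)
                d0 = woods.distance(c)
                if not lo_d <= d0 <= hi_d:
                    continue
                if any(math.hypot(cx - px, cy - py) < 300.0 for px, py in centers):
                    continue
                near = nearest_points(woods, c)[0]
                ux, uy = cx - near.x, cy - near.y
                norm = math.hypot(ux, uy)
                ux, uy = ux / norm, uy / norm
                pts = [
                    (
                        cx + (j - half) * design.point_spacing * ux,
                        cy + (j - half) * design.point_spacing * uy,
                    )
                    for j in range(design.points_per_field)
                ]
                ok = all(
                    woods.distance(Point(px, py)) > 10.0
                    and ox <= px <= ox + ex
                    and oy <= py <= oy + ey
                    for px, py in pts
                )
                if not ok:
                    continue
                centers.append((cx, cy))
                label = f"{site}-{f + 1:02d}"
                for px, py in pts:
                    rows.append({"field": label, "site": site, "x": px, "y": py})
                break
            else:
                raise RuntimeError(f"could not place field {f} in site {site}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study


def expected_means(
    skeleton: pd.DataFrame,
    truth: GeneratingTruth,
    raster: WoodRaster,
    cutoff: float = CUTOFF_DEFAULT,
) -> np.ndarray:
    """Forward-model mean mu(t, i) for each row of a points x dates
    skeleton (columns field, site, date, x, y)."""
    spec = truth.spec("split")
    mus = np.empty(len(skeleton))
    for i, (_, row) in enumerate(skeleton.iterrows()):
        pt = SamplingPoint("p", str(row["field"]), str(row["site"]), row["x"], row["y"])
        mus[i] = disp.expected_abundance(
            spec,
            truth.params_for_site(str(row["site"])),
            truth.log_size(row),
            pt,
            int(row["date"]),
            raster,
            cutoff=cutoff,
        )
    return mus


def draw_counts(mus: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with mean mu and size theta."""
    mus = np.asarray(mus, dtype=float)
    p = theta / (theta + mus)
    return rng.negative_binomial(theta, p)


@dataclass
class SimulatedStudy:
    table: pd.DataFrame
    polygons: list
    raster: WoodRaster
    skeleton: pd.DataFrame
    mu: np.ndarray
    truth: GeneratingTruth
    design: StudyDesign


def simulate_study(
    design: StudyDesign,
    truth: GeneratingTruth,
    seed: int,
    landscape=None,
    cutoff: float = CUTOFF_DEFAULT,
) -> SimulatedStudy:
    """Generate a complete synthetic study: landscape, sampling design
    and NB counts around kernel-driven means."""
    truth.validate(design.n_dates)
    ss = np.random.SeedSequence(seed)
    s_land, s_fields, s_counts = ss.spawn(3)
    if landscape is None:
        polygons, raster = simulate_landscape(
            design, int(s_land.generate_state(1)[0] % 2**31)
        )
    else:
        polygons, raster = landscape
    points = simulate_fields(
        design, polygons, int(s_fields.generate_state(1)[0] % 2**31)
    )
    frames = []
    for t in range(1, design.n_dates + 1):
        f = points.copy()
        f["date"] = t
        frames.append(f)
    skeleton = pd.concat(frames, ignore_index=True)
    mus = expected_means(skeleton, truth, raster, cutoff=cutoff)
    rng = np.random.default_rng(s_counts)
    counts = draw_counts(mus, truth.theta, rng)
    table = skeleton.assign(count=counts)[["field", "site", "date", "count", "x", "y"]]
    return SimulatedStudy(
        table=table,
        polygons=polygons,
        raster=raster,
        skeleton=skeleton,
        mu=mus,
        truth=truth,
        design=design,
    )
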