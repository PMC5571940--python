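"""Calibration and recovery studies.

These are the package's own checks that the estimation machinery works
under the study conditions it was built for: kernel closed forms by
quadrature, parameter and model recovery on synthetic studies,
convergence-diagnostic calibration on iid chains, and the buffer-radius
scan behaviour.  They are exercised both by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.integrate import quad

from . import dispersal as disp
from .buffer_glm import buffer_areas, fit_buffer_model, scan_buffer_radius
from .inference import fit_model, geweke_z, raftery_lewis
from .model_space import ModalityGrid, enumerate_models, fit_all
from .synthetic import (
    GeneratingTruth,
    StudyDesign,
    draw_counts,
    expected_means,
    field_effect_truth,
    baseline_truth,
    simulate_fields,
    simulate_landscape,
    simulate_study,
)

RECOVERY_DESIGN = StudyDesign(n_sites=4, fields_per_site=6)


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# kernels


def kernel_quadrature_report(deltas=(0.5, 1.0, 2.0)) -> dict:
    """Radial quadrature of both kernel families: total mass vs 1 and
    mean radial distance vs the closed forms (2*delta exponential,
    sqrt(pi)/2*delta gaussian)."""
    max_norm_err = 0.0
    max_mean_err = 0.0
    for family in (disp.GAUSSIAN, disp.EXPONENTIAL):
        for delta in deltas:
            mass, _ = quad(
                lambda r: disp.kernel_density(r, delta, family) * 2 * math.pi * r,
                0, np.inf,
            )
            mean, _ = quad(
                lambda r: r * disp.kernel_density(r, delta, family) * 2 * math.pi * r,
                0, np.inf,
            )
            closed = disp.mean_dispersal_distance(
                disp.DispersalParams(beta_d=delta), 1, family
            )
            max_norm_err = max(max_norm_err, abs(mass - 1.0))
            max_mean_err = max(max_mean_err, abs(mean - closed))
    return {
        "max_normalization_error": max_norm_err,
        "max_mean_distance_error": max_mean_err,
        "n_cases": 2 * len(deltas),
    }


# ---------------------------------------------------------------------------
# diagnostics calibration


def diagnostics_calibration(seed: int, n_chains: int = 200, n: int = 10000) -> dict:
    """Geweke pass rate on iid standard-normal chains and the
    Raftery-Lewis minimum run length / iid dependence factor."""
    rng = np.random.default_rng(seed)
    passes = 0
    for _ in range(n_chains):
        z = geweke_z(rng.normal(size=n))
        passes += abs(z) < 1.96
    rl = raftery_lewis(rng.normal(size=20000))
    return {
        "geweke_pass_rate_pct": 100.0 * passes / n_chains,
        "n_chains": n_chains,
        "rl_n_min": rl.n_min,
        "rl_iid_dependence_factor": rl.dependence_factor,
    }


# ---------------------------------------------------------------------------
# parameter recovery


def parameter_recovery_study(
    seed: int,
    n_reps: int = 20,
    design: StudyDesign = RECOVERY_DESIGN,
    truth: GeneratingTruth | None = None,
    block_size: int = 5000,
    max_blocks: int = 4,
) -> dict:
    """Simulate studies under the default truth and refit the generating
    spec; report credible-interval coverage of beta_d and how often the
    posterior median lands within 25% of the truth."""
    truth = truth or baseline_truth()
    spec = truth.spec("split")
    bd_true = truth.params.beta_d
    rows = []
    for rep, s in enumerate(_sub_seeds(seed, n_reps)):
        study = simulate_study(design, truth, s)
        fit = fit_model(
            study.table, study.raster, spec,
            seed=s + 1, block_size=block_size, max_blocks=max_blocks,
        )
        est = fit.estimates.loc["beta_d"]
        j = fit.chain.param_names.index("beta_d")
        med = float(np.median(fit.chain.retained[:, j]))
        rows.append(
            {
                "rep": rep,
                "beta_d_true": bd_true,
                "median": med,
                "lo": est["lo"],
                "hi": est["hi"],
                "covered": bool(est["lo"] <= bd_true <= est["hi"]),
                "rel_err": abs(med - bd_true) / bd_true,
                "converged": fit.converged,
            }
        )
    details = pd.DataFrame(rows)
    return {
        "coverage_count": int(details["covered"].sum()),
        "median_within_25pct_count": int((details["rel_err"] <= 0.25).sum()),
        "n_reps": n_reps,
        "details": details,
    }


# ---------------------------------------------------------------------------
# model recovery


def recovery_subgrid() -> list:
    """The restricted modality grid used for model-recovery simulations:
    {date+field, date:site} x {gaussian, exponential} x {split, merged,
    none}, origin = area, site-independent dispersal."""
    return enumerate_models(
        ModalityGrid(
            size_factors=("date+field", "date:site"),
            origins=("area",),
            structures=("split", "merged", "none"),
            kernels=("gaussian", "exponential"),
            site_dependent=(False,),
        )
    )


def model_recovery_study(
    seed: int,
    n_reps: int = 20,
    design: StudyDesign = RECOVERY_DESIGN,
    block_size: int = 2500,
    max_blocks: int = 3,
) -> dict:
    """Simulate under (date+field, area, split, gaussian,
    site-independent) with a short dispersal scale and fit the restricted
    subgrid; count how often the generating modality wins the AIC ranking
    and how often every geometry-free ("none") spec ranks below it."""
    generating = disp.ModelSpec(
        size_factor="date+field", origin="area", point_structure="split",
        kernel="gaussian", site_dependent=False,
    )
    specs = recovery_subgrid()
    rows = []
    for rep, s in enumerate(_sub_seeds(seed, n_reps)):
        ss = np.random.SeedSequence(s)
        s_land, s_fields, s_truth, s_counts = [
            int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
        ]
        polygons, raster = simulate_landscape(design, s_land)
        points = simulate_fields(design, polygons, s_fields)
        truth = field_effect_truth(
            sorted(points["field"].unique()), s_truth, n_dates=design.n_dates
        )
        frames = []
        for t in range(1, design.n_dates + 1):
            f = points.copy()
            f["date"] = t
            frames.append(f)
        skeleton = pd.concat(frames, ignore_index=True)
        mus = expected_means(skeleton, truth, raster)
        counts = draw_counts(mus, truth.theta, np.random.default_rng(s_counts))
        table = skeleton.assign(count=counts)[
            ["field", "site", "date", "count", "x", "y"]
        ]
        ranking = fit_all(
            specs, table, raster, seed=s,
            block_size=block_size, max_blocks=max_blocks,
        )
        df = ranking.table
        gen_rows = df.index[
            (df["size_factor"] == generating.size_factor)
            & (df["point_structure"] == "split")
            & (df["kernel"] == "gaussian")
        ]
        rank = int(gen_rows[0])
        gen_aic = df.loc[rank, "aic"]
        none_aics = df.loc[df["point_structure"] == "none", "aic"]
        rows.append(
            {
                "rep": rep,
                "rank": rank,
                "top": rank == 0,
                "none_below": bool((none_aics > gen_aic).all()),
            }
        )
    details = pd.DataFrame(rows)
    return {
        "top_rank_count": int(details["top"].sum()),
        "none_below_count": int(details["none_below"].sum()),
        "n_reps": n_reps,
        "n_specs": len(specs),
        "details": details,
    }


# ---------------------------------------------------------------------------
# buffer scan


def buffer_scan_study(
    seed: int,
    n_reps: int = 20,
    design: StudyDesign = RECOVERY_DESIGN,
    size_factor: str = "site:date",
) -> dict:
    """Scan the buffer radius on kernel-simulated data (mean dispersal
    distance ~1.2 km): the selected radius should be interior to the
    0.2-5 km grid; also verify the offset reparameterization identity
    (scaling all areas by c shifts every coefficient by -log c)."""
    truth = baseline_truth()
    interior = 0
    radii = []
    shift_err = math.nan
    for rep, s in enumerate(_sub_seeds(seed, n_reps)):
        study = simulate_study(design, truth, s)
        scan = scan_buffer_radius(study.table, study.raster, size_factor)
        r = scan.best_radius_km
        radii.append(r)
        if 0.2 + 1e-9 < r < 5.0 - 1e-9:
            interior += 1
        if rep == 0:
            areas = buffer_areas(study.table, study.raster, 2.0)
            base = fit_buffer_model(
                study.table, study.raster, 2.0, size_factor, areas=areas
            )
            scaled = fit_buffer_model(
                study.table, study.raster, 2.0, size_factor, areas=areas * 0.5
            )
            ok = ~np.isnan(base.coef)
            shift_err = float(
                np.max(np.abs(scaled.coef[ok] - base.coef[ok] - math.log(2.0)))
            )
    return {
        "interior_count": interior,
        "n_reps": n_reps,
        "radii": radii,
        "offset_shift_max_abs_error": shift_err,
    }
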