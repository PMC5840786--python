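"""Simulation studies that check the pipeline's statistical calibration.

These are the package's self-validation experiments: null calibration of
the Monte Carlo decision rule, recovery of planted scenario effects,
smoothness-estimator accuracy, and GLM calibration/power on simulated
cohorts. They are run by the test suite and by the acceptance script;
the default problem sizes (32-cube grids, 500-iteration nulls, tens of
replicates) are desk-scale profiles of the full-scale procedure
(MNI-like grids, 5000 iterations).
"""

from __future__ import annotations

import numpy as np

from .conjunction import (
    SCENARIOS,
    build_threshold_grid,
    overlap_curve_from_values,
)
from .group_zmaps import fit_voxelwise_glm
from .null_model import monte_carlo_null
from .pipeline import analyze_pair
from .synthetic_data import (
    CohortSpec,
    FieldSpec,
    PlantedEffect,
    _sigma_vox,
    _smooth_standardized_field,
    cohort_derivative_maps,
    generate_smooth_field,
    plant_zmap_pair,
    simulate_cohort,
)
from .null_model import estimate_fwhm
from .volume_io import MaskedVolume

__all__ = [
    "null_calibration_study",
    "scenario_recovery_study",
    "fwhm_recovery_study",
    "glm_calibration_study",
    "glm_recovery_study",
]


def null_calibration_study(
    n_replicates: int = 200,
    iterations: int = 500,
    shape=(32, 32, 32),
    fwhm_mm: float = 6.0,
    consistency: float = 0.70,
    seed: int = 0,
) -> dict:
    """False-positive behavior of the decision rule under the global null.

    Builds one Monte Carlo null at the matched smoothness, then draws
    ``n_replicates`` observed pairs from the same null and measures (a)
    the mean per-threshold rate at which the observed overlap exceeds
    the 99.5th band and (b) the family-wise rate at which any of the
    four scenarios is declared significant.
    """
    ss = np.random.SeedSequence([seed, 101])
    null_seed = int(ss.generate_state(1)[0] % (2**31))
    spec = FieldSpec(shape=tuple(shape), fwhm_mm=fwhm_mm, seed=0)
    mask = spec.make_mask()
    template = MaskedVolume(np.zeros(spec.shape), spec.affine, mask)
    grid = build_threshold_grid()
    null = monte_carlo_null(template, fwhm_mm, grid, iterations=iterations, seed=null_seed)
    band = null.band(99.5)
    required = int(np.ceil(consistency * len(grid)))

    rng = np.random.default_rng(ss.spawn(1)[0])
    sigma = _sigma_vox(fwhm_mm, spec.voxel_size_mm)
    exceed_total = np.zeros(len(grid))
    n_familywise = 0
    for _ in range(n_replicates):
        a = _smooth_standardized_field(rng, spec.shape, sigma, mask)[mask]
        b = _smooth_standardized_field(rng, spec.shape, sigma, mask)[mask]
        any_sig = False
        for name, sc in SCENARIOS.items():
            pct, *_ = overlap_curve_from_values(
                sc.a_sign * a, sc.b_sign * b, grid.z_values
            )
            exceed = pct > band
            if name == "EMB1":
                exceed_total += exceed
            if int(exceed.sum()) >= required:
                any_sig = True
        n_familywise += any_sig
    return {
        "mean_exceedance_rate": float(exceed_total.mean() / n_replicates),
        "per_threshold_rates": exceed_total / n_replicates,
        "familywise_rate": n_familywise / n_replicates,
        "n_replicates": n_replicates,
        "iterations": iterations,
    }


def scenario_recovery_study(
    n_replicates: int = 20,
    amplitude_z: float = 6.0,
    radius_voxels: float = 4.0,
    iterations: int = 500,
    shape=(32, 32, 32),
    fwhm_mm: float = 6.0,
    seed: int = 0,
) -> dict:
    """Planted-effect recovery: each scenario detected as itself only.

    For every scenario and replicate, plants one effect of peak |Z| =
    ``amplitude_z`` at the mask center and runs the full pipeline
    (smoothness estimation, matched Monte Carlo null, decision). A
    replicate counts as recovered when the planted scenario is declared
    significant and the other three are not.
    """
    ss = np.random.SeedSequence([seed, 202])
    center = tuple(int(s) // 2 for s in shape)
    results: dict[str, dict] = {}
    child_seeds = ss.generate_state(2 * 4 * n_replicates) % (2**31)
    k = 0
    for name, sc in SCENARIOS.items():
        hits = 0
        own_sig = 0
        for _ in range(n_replicates):
            field_seed, null_seed = int(child_seeds[k]), int(child_seeds[k + 1])
            k += 2
            spec = FieldSpec(shape=tuple(shape), fwhm_mm=fwhm_mm, seed=field_seed)
            eff = PlantedEffect(center, radius_voxels, sc.a_sign * abs(amplitude_z), name)
            pair = plant_zmap_pair(spec, [eff])
            out = analyze_pair(pair, iterations=iterations, seed=null_seed)
            sig = {s: out["results"][s].significant for s in SCENARIOS}
            own_sig += sig[name]
            if sig[name] and not any(v for s, v in sig.items() if s != name):
                hits += 1
        results[name] = {
            "recovered_uniquely": hits,
            "own_scenario_significant": own_sig,
            "n_replicates": n_replicates,
        }
    total = sum(r["recovered_uniquely"] for r in results.values())
    results["overall_recovery_rate"] = total / (4 * n_replicates)
    return results


def fwhm_recovery_study(
    n_seeds: int = 20,
    fwhm_mm: float = 6.0,
    shape=(48, 48, 48),
    voxel_size_mm: float = 3.0,
    seed: int = 0,
) -> dict:
    """Mean recovered FWHM for fields smoothed at a known FWHM."""
    base = int(np.random.SeedSequence([seed, 303]).generate_state(1)[0] % (2**30))
    ests = []
    for s in range(n_seeds):
        vol = generate_smooth_field(
            FieldSpec(
                shape=tuple(shape),
                voxel_size_mm=(voxel_size_mm,) * 3,
                fwhm_mm=fwhm_mm,
                seed=base + s,
            )
        )
        ests.append(estimate_fwhm(vol).combined_fwhm_mm)
    return {
        "true_fwhm_mm": fwhm_mm,
        "mean_recovered_fwhm_mm": float(np.mean(ests)),
        "relative_error": float(abs(np.mean(ests) - fwhm_mm) / fwhm_mm),
        "n_seeds": n_seeds,
    }


def _cohort_zmap(effect_size: float, seed: int, n_per_group: int = 20):
    spec = CohortSpec(
        n_per_group=n_per_group,
        effect_metric="fALFF",
        effect_size=effect_size,
        seed=seed,
    )
    ds = simulate_cohort(spec)
    maps = cohort_derivative_maps(ds)
    zmap = fit_voxelwise_glm(maps, ds.phenotype, positive_group=spec.group_labels[1])
    return zmap, ds


def glm_calibration_study(n_replicates: int = 10, seed: int = 0) -> dict:
    """|Z| > 1.96 rate of the voxel-wise GLM on effect-free cohorts."""
    base = int(np.random.SeedSequence([seed, 404]).generate_state(1)[0] % (2**30))
    rates = [
        float(np.mean(np.abs(_cohort_zmap(0.0, base + r)[0].volume.values()) > 1.96))
        for r in range(n_replicates)
    ]
    return {
        "mean_rate": float(np.mean(rates)),
        "rates": rates,
        "nominal": 0.05,
        "n_replicates": n_replicates,
    }


def glm_recovery_study(
    n_replicates: int = 10, effect_size: float = 1.5, seed: int = 0
) -> dict:
    """Power check: planted d = 1.5 gives region mean Z above 3."""
    base = int(np.random.SeedSequence([seed, 505]).generate_state(1)[0] % (2**30))
    region_means = []
    outside_means = []
    for r in range(n_replicates):
        zmap, ds = _cohort_zmap(effect_size, base + r)
        region = ds.effect_mask & zmap.volume.mask
        outside = zmap.volume.mask & ~ds.effect_mask
        region_means.append(float(zmap.volume.data[region].mean()))
        outside_means.append(float(zmap.volume.data[outside].mean()))
    region_means = np.array(region_means)
    return {
        "region_mean_z": [float(x) for x in region_means],
        "mean_region_z": float(region_means.mean()),
        "mean_outside_z": float(np.mean(outside_means)),
        "n_above_3": int((region_means > 3.0).sum()),
        "n_replicates": n_replicates,
    }
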