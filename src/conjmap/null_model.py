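"""Smoothness-matched Monte Carlo null for the overlap statistic.

The null distribution of random overlaps: per iteration, two independent
Gaussian random fields are generated at the target smoothness within the
analysis mask, thresholded along the full grid, and their overlap
percentage recorded per threshold. Observed overlap curves are compared
against the 99.5th-percentile band; a scenario is significant when its
curve lies strictly above the band at >= 70% of all thresholds.

Smoothness is estimated with the classic Gaussian-field estimator from
within-mask first differences (per axis, then combined as a geometric
mean), and averaged arithmetically across the two observed maps — the
analytic counterpart of estimating per-map FWHM and matching simulations
to the average. The spatial-autocorrelation-function variant of modern
smoothness estimators is deliberately not modeled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .conjunction import (
    SCENARIOS,
    OverlapCurve,
    ScenarioSpec,
    ThresholdGrid,
    ZMapPair,
    conjunction_mask,
    overlap_curve_from_values,
    scenario_overlap_curves,
)
from .synthetic_data import _sigma_vox, _smooth_standardized_field
from .volume_io import MaskedVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothnessEstimate",
    "NullDistribution",
    "ScenarioResult",
    "estimate_fwhm",
    "average_smoothness",
    "monte_carlo_null",
    "decide_significance",
    "permutation_null",
]

PERCENTILES = (0.5, 50.0, 99.5)


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM (mm); NaN marks a below-resolution axis."""

    fwhm_mm: tuple[float, float, float]
    combined_fwhm_mm: float
    source: str = ""

    @property
    def below_resolution(self) -> tuple[bool, bool, bool]:
        return tuple(bool(np.isnan(f)) for f in self.fwhm_mm)  # type: ignore


@dataclass
class NullDistribution:
    """iterations x thresholds matrix of null overlap percents + bands."""

    overlaps: np.ndarray
    grid: ThresholdGrid
    bands: dict
    iterations: int
    seed: int | None
    target_fwhm_mm: float

    def band(self, pct: float) -> np.ndarray:
        return self.bands[pct]


@dataclass
class ScenarioResult:
    """Significance decision for one (map-pair, scenario)."""

    scenario: ScenarioSpec
    exceedance_count: int
    required_count: int
    significant: bool
    n_thresholds: int
    display_mask: np.ndarray | None = None
    display_z: float | None = None


def estimate_fwhm(vol: MaskedVolume, min_pairs: int = 100) -> SmoothnessEstimate:
    """Classic Gaussian-field smoothness estimate from first differences.

    Per axis: FWHM = voxel_size * sqrt(-2 ln 2 / ln(rho)) with
    rho = 1 - vardiff / (2 var), vardiff the variance of within-mask
    neighbor differences along that axis and var the within-mask field
    variance. rho <= 0 (white or rougher than voxel scale) is reported
    as below-resolution (NaN). Combined value: geometric mean of the
    defined axes. Scale-invariant by construction.
    """
    mask = vol.mask
    vals = vol.values()
    if vals.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} in-mask voxels, got {vals.size}")
    var = vals.var()
    if var == 0:
        raise ValueError("constant field; smoothness undefined")

    fwhms = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair_mask = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        if pair_mask.sum() < min_pairs:
            raise ValueError(
                f"axis {ax}: only {int(pair_mask.sum())} usable in-mask voxel "
                f"pairs (< {min_pairs})"
            )
        diffs = (vol.data[tuple(sl_hi)] - vol.data[tuple(sl_lo)])[pair_mask]
        vardiff = diffs.var() + diffs.mean() ** 2  # mean-square difference
        rho = 1.0 - vardiff / (2.0 * var)
        if rho <= 0.0:
            fwhms.append(np.nan)
        else:
            fwhms.append(
                float(vol.voxel_size_mm[ax] * math.sqrt(-2.0 * math.log(2.0) / math.log(rho)))
            )
    defined = [f for f in fwhms if not np.isnan(f)]
    combined = float(np.exp(np.mean(np.log(defined)))) if defined else float("nan")
    return SmoothnessEstimate(tuple(fwhms), combined)  # type: ignore[arg-type]


def average_smoothness(a: SmoothnessEstimate, b: SmoothnessEstimate) -> SmoothnessEstimate:
    """Element-wise arithmetic mean of two smoothness estimates."""
    fwhm = tuple(
        float(np.mean([x, y])) for x, y in zip(a.fwhm_mm, b.fwhm_mm)
    )
    defined = [f for f in fwhm if not np.isnan(f)]
    combined = float(np.exp(np.mean(np.log(defined)))) if defined else float("nan")
    return SmoothnessEstimate(fwhm, combined, source=f"mean({a.source},{b.source})")  # type: ignore[arg-type]


def monte_carlo_null(
    template: MaskedVolume,
    target_fwhm_mm: float,
    grid: ThresholdGrid,
    iterations: int = 5000,
    seed: int | None = None,
) -> NullDistribution:
    """Null distribution of random overlaps at matched smoothness.

    Each iteration draws two independent smooth standardized fields on
    the template's mask, thresholds both along the grid (one directional
    tail), and records the overlap percentage per threshold. One shared
    null serves all four scenarios: the simulated fields are sign-
    symmetric, so the four directional tails are exchangeable. Percentile
    bands use the linear-interpolation empirical quantile.
    """
    if iterations < 100:
        logger.warning(
            "monte_carlo_null: %d iterations is below the recommended minimum "
            "of 100; percentile bands will be unstable",
            iterations,
        )
    mask = template.mask
    sigma = _sigma_vox(target_fwhm_mm, template.voxel_size_mm)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_thr = len(grid)
    overlaps = np.empty((iterations, n_thr))
    for i in range(iterations):
        a = _smooth_standardized_field(rng, mask.shape, sigma, mask)[mask]
        b = _smooth_standardized_field(rng, mask.shape, sigma, mask)[mask]
        overlaps[i], *_ = overlap_curve_from_values(a, b, grid.z_values)
    bands = {p: np.percentile(overlaps, p, axis=0) for p in PERCENTILES}
    return NullDistribution(
        overlaps=overlaps,
        grid=grid,
        bands=bands,
        iterations=iterations,
        seed=seed,
        target_fwhm_mm=float(target_fwhm_mm),
    )


def decide_significance(
    curve: OverlapCurve,
    null: NullDistribution,
    consistency: float = 0.70,
    pair: ZMapPair | None = None,
    display_z: float = 2.58,
) -> ScenarioResult:
    """Consistency decision against the 99.5th-percentile null band.

    Counts thresholds where the observed overlap lies *strictly* above
    the band (ties break conservatively); significant iff the count
    reaches ceil(consistency * n_thresholds) — 350 of 500 at the
    defaults. If the pair is supplied, the conjunction mask at the
    display threshold is attached.
    """
    if len(curve.grid) != len(null.grid) or not np.allclose(
        curve.grid.p_values, null.grid.p_values
    ):
        raise ValueError("curve and null are on different threshold grids")
    n_thr = len(curve.grid)
    required = math.ceil(consistency * n_thr)
    exceed = int((curve.overlap_percent > null.band(99.5)).sum())
    mask = None
    if pair is not None:
        mask = conjunction_mask(pair, curve.scenario, display_z)
    return ScenarioResult(
        scenario=curve.scenario,
        exceedance_count=exceed,
        required_count=required,
        significant=exceed >= required,
        n_thresholds=n_thr,
        display_mask=mask,
        display_z=display_z if mask is not None else None,
    )


def permutation_null(
    maps_a,
    pheno_a,
    maps_b,
    pheno_b,
    grid: ThresholdGrid,
    n_perm: int = 1000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, NullDistribution]:
    """Label-permutation alternative to the Monte Carlo null.

    Requires subject-level inputs: per-subject derivative maps and
    phenotype tables for both samples. Each permutation shuffles the
    group labels within each sample, refits both voxel-wise GLMs, and
    recomputes the four scenario overlap curves. Returns one
    NullDistribution per scenario.
    """
    from .group_zmaps import fit_voxelwise_glm

    if maps_a is None or maps_b is None or pheno_a is None or pheno_b is None:
        raise ValueError(
            "permutation_null requires subject-level derivative maps and "
            "phenotype tables for both samples; Z-maps alone are not enough"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_thr = len(grid)
    overlaps = {name: np.empty((n_perm, n_thr)) for name in SCENARIOS}
    pos_a = sorted(pheno_a["group"].unique())[-1]
    pos_b = sorted(pheno_b["group"].unique())[-1]
    for p in range(n_perm):
        pa = pheno_a.copy()
        pb = pheno_b.copy()
        pa["group"] = rng.permutation(pa["group"].to_numpy())
        pb["group"] = rng.permutation(pb["group"].to_numpy())
        za = fit_voxelwise_glm(maps_a, pa, positive_group=pos_a, mask=mask)
        zb = fit_voxelwise_glm(maps_b, pb, positive_group=pos_b, mask=mask)
        pair = ZMapPair(za.volume, zb.volume)
        curves = scenario_overlap_curves(pair, grid)
        for name, curve in curves.items():
            overlaps[name][p] = curve.overlap_percent
    out = {}
    for name, mat in overlaps.items():
        bands = {q: np.percentile(mat, q, axis=0) for q in PERCENTILES}
        out[name] = NullDistribution(
            overlaps=mat,
            grid=grid,
            bands=bands,
            iterations=n_perm,
            seed=seed,
            target_fwhm_mm=float("nan"),
        )
    return out
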