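"""Seed-controlled synthetic inputs for the conjunction pipeline.

Three families of generators:

* smoothed Gaussian random Z-fields on a masked grid at a controlled
  FWHM (the building block of the Monte Carlo null);
* pairs of Z-maps with planted co-localized directional effects
  realizing each of the four overlap scenarios (EMB1/EMB2/GI1/GI2);
* small 4D cohorts with a group difference injected into one of the
  five R-fMRI derivatives, plus a phenotype table.

Everything is a pure function of its spec + seed: a single top-level
seed is fanned out through ``numpy.random.SeedSequence`` in a fixed
order, so identical specs reproduce identical outputs bit for bit.

Planted effects are isotropic Gaussian bumps truncated at 3 sigma (with
sigma = radius_voxels / 2), not hard spheres: the peak added Z equals
the requested amplitude and the ground-truth voxel set is the sphere of
``radius_voxels`` around the center.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .conjunction import SCENARIOS, ZMapPair
from .rfmri_metrics import (
    FWHM_TO_SIGMA,
    METRIC_NAMES,
    MetricConfig,
    compute_derivative,
)
from .volume_io import MaskedVolume, write_mask, write_volume

logger = logging.getLogger(__name__)

__all__ = [
    "FieldSpec",
    "PlantedEffect",
    "CohortSpec",
    "CohortDataset",
    "generate_smooth_field",
    "plant_zmap_pair",
    "simulate_cohort",
    "cohort_derivative_maps",
    "make_synthetic_atlas",
    "write_pair",
]


# --------------------------------------------------------------------------
# smooth random fields


@dataclass
class FieldSpec:
    """Geometry + smoothness of one simulated Z-field."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    fwhm_mm: float = 6.0
    mask_kind: str = "ellipsoid"
    custom_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError("each shape component must be >= 8")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if self.mask_kind not in ("full", "ellipsoid", "custom"):
            raise ValueError("mask_kind must be full, ellipsoid or custom")
        if self.mask_kind == "custom" and self.custom_mask is None:
            raise ValueError("mask_kind='custom' requires custom_mask")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        # center the grid on the world origin
        aff[:3, 3] = -0.5 * (np.array(self.shape) - 1) * np.array(self.voxel_size_mm)
        return aff

    def make_mask(self) -> np.ndarray:
        if self.mask_kind == "full":
            return np.ones(self.shape, dtype=bool)
        if self.mask_kind == "custom":
            m = np.asarray(self.custom_mask, dtype=bool)
            if m.shape != tuple(self.shape):
                raise ValueError("custom_mask shape mismatch")
            return m
        grids = np.indices(self.shape).astype(float)
        center = (np.array(self.shape) - 1) / 2.0
        semi = (np.array(self.shape) - 2) / 2.0
        d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
        return d2 <= 1.0


def _sigma_vox(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    return fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)


def _smooth_standardized_field(
    rng: np.random.Generator, shape, sigma_vox: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """White noise -> Gaussian smoothing -> re-standardize within mask.

    Smoothing happens on the full grid before masking (masking first
    would distort smoothness at the mask edge).
    """
    data = rng.standard_normal(shape)
    if np.any(sigma_vox > 0):
        data = ndimage.gaussian_filter(data, sigma_vox)
    vals = data[mask]
    data = (data - vals.mean()) / vals.std()
    return np.where(mask, data, 0.0)


def generate_smooth_field(
    spec: FieldSpec, rng: np.random.Generator | None = None
) -> MaskedVolume:
    """Smoothed, within-mask standardized Gaussian random field.

    Voxels outside the mask are zero. ``rng`` overrides the spec seed
    (used by the Monte Carlo loop to stream many fields off one seed).
    """
    sigma = _sigma_vox(spec.fwhm_mm, spec.voxel_size_mm)
    # kernel support (4 sigma) must fit inside the grid
    if np.any(np.ceil(4 * sigma) >= np.array(spec.shape)):
        max_fwhm = (
            np.min((np.array(spec.shape) - 1) / 4.0 * np.asarray(spec.voxel_size_mm))
            / FWHM_TO_SIGMA
        )
        raise ValueError(
            f"fwhm_mm={spec.fwhm_mm} too large for grid {spec.shape}: "
            f"kernel support exceeds the grid (max ~{max_fwhm:.1f} mm)"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    mask = spec.make_mask()
    data = _smooth_standardized_field(rng, spec.shape, sigma, mask)
    return MaskedVolume(data, spec.affine, mask)


# --------------------------------------------------------------------------
# planted Z-map pairs


@dataclass
class PlantedEffect:
    """A co-localized directional effect added to both maps of a pair.

    ``scenario`` fixes the sign pair added to (map A, map B):
    EMB1 -> (+,+), EMB2 -> (-,-), GI1 -> (+,-), GI2 -> (-,+).
    ``amplitude_z`` is the peak added Z; its sign must match the
    scenario's map-A direction. ``jitter_voxels`` offsets the map-B bump
    center along the first axis.
    """

    center_voxel: tuple[int, int, int]
    radius_voxels: float
    amplitude_z: float
    scenario: str
    jitter_voxels: int = 0

    def __post_init__(self) -> None:
        if self.radius_voxels <= 0:
            raise ValueError("radius_voxels must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.jitter_voxels < 0:
            raise ValueError("jitter_voxels must be non-negative")
        if self.amplitude_z == 0:
            raise ValueError("amplitude_z must be non-zero")
        a_sign = SCENARIOS[self.scenario].a_sign
        if np.sign(self.amplitude_z) != a_sign:
            raise ValueError(
                f"amplitude_z sign {np.sign(self.amplitude_z):+.0f} contradicts "
                f"scenario {self.scenario} (map-A direction "
                f"{SCENARIOS[self.scenario].a_direction})"
            )

    @property
    def sigma_voxels(self) -> float:
        return self.radius_voxels / 2.0

    @property
    def truncation_radius(self) -> float:
        return 3.0 * self.sigma_voxels


def _gaussian_bump(shape, center, sigma: float, trunc: float) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    bump = np.exp(-d2 / (2.0 * sigma**2))
    bump[d2 > trunc**2] = 0.0
    return bump


def _sphere(shape, center, radius: float) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def plant_zmap_pair(
    spec: FieldSpec,
    effects: list[PlantedEffect],
    noise_fwhm_mm: float | None = None,
) -> ZMapPair:
    """Two independent smooth null fields with planted scenario effects.

    The fields are standardized *before* bumps are added, so each
    effect's peak added Z equals its amplitude. Ground truth (scenario,
    centers, sphere voxel set) is recorded on the returned pair.
    """
    if noise_fwhm_mm is None:
        noise_fwhm_mm = spec.fwhm_mm
    mask = spec.make_mask()
    shape = tuple(spec.shape)

    # preconditions: inside mask, pairwise non-overlapping (at truncation radii)
    for eff in effects:
        for center in _effect_centers(eff):
            if not _sphere(shape, center, eff.radius_voxels)[mask].any() or not mask[
                tuple(np.clip(np.round(center).astype(int), 0, np.array(shape) - 1))
            ]:
                raise ValueError(f"effect at {center} lies outside the mask")
            sphere = _sphere(shape, center, eff.radius_voxels)
            if (sphere & ~mask).any():
                raise ValueError(
                    f"effect sphere at {center} extends outside the mask"
                )
    for i, e1 in enumerate(effects):
        for e2 in effects[i + 1 :]:
            dist = np.linalg.norm(
                np.array(e1.center_voxel, float) - np.array(e2.center_voxel, float)
            )
            reach = e1.truncation_radius + e2.truncation_radius + max(
                e1.jitter_voxels, e2.jitter_voxels
            )
            if dist <= reach:
                raise ValueError(
                    f"effects at {e1.center_voxel} and {e2.center_voxel} overlap"
                )

    ss = np.random.SeedSequence(spec.seed)
    rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(2))
    sigma = _sigma_vox(noise_fwhm_mm, spec.voxel_size_mm)
    data_a = _smooth_standardized_field(rng_a, shape, sigma, mask)
    data_b = _smooth_standardized_field(rng_b, shape, sigma, mask)

    ground_truth = []
    for eff in effects:
        sc = SCENARIOS[eff.scenario]
        mag = abs(eff.amplitude_z)
        center_a, center_b = _effect_centers(eff)
        bump_a = _gaussian_bump(shape, center_a, eff.sigma_voxels, eff.truncation_radius)
        bump_b = _gaussian_bump(shape, center_b, eff.sigma_voxels, eff.truncation_radius)
        data_a += sc.a_sign * mag * np.where(mask, bump_a, 0.0)
        data_b += sc.b_sign * mag * np.where(mask, bump_b, 0.0)
        truth = _sphere(shape, center_a, eff.radius_voxels) | _sphere(
            shape, center_b, eff.radius_voxels
        )
        ground_truth.append(
            {
                "scenario": eff.scenario,
                "center_a": tuple(center_a),
                "center_b": tuple(center_b),
                "amplitude_z": eff.amplitude_z,
                "radius_voxels": eff.radius_voxels,
                "voxels": truth & mask,
            }
        )

    pair = ZMapPair(
        MaskedVolume(data_a, spec.affine, mask),
        MaskedVolume(data_b, spec.affine, mask),
        ground_truth=ground_truth,
    )
    return pair


def _effect_centers(eff: PlantedEffect):
    center_a = np.array(eff.center_voxel, dtype=float)
    center_b = center_a.copy()
    center_b[0] += eff.jitter_voxels
    return center_a, center_b


# --------------------------------------------------------------------------
# 4D cohorts


@dataclass
class CohortSpec:
    """A two-group cohort with a group difference in one derivative.

    ``effect_size`` is the standardized voxel-wise group difference of
    the chosen derivative inside the effect region, in within-group SD
    units; the generator calibrates the injected-signal amplitude
    empirically on the cohort's own noise to realize it. Covariates
    (age, site, mean framewise displacement) are generated independently
    of group unless ``confound_group_meanfd`` is set.
    """

    n_per_group: int = 20
    n_timepoints: int = 64
    tr_seconds: float = 2.0
    effect_metric: str = "fALFF"
    effect_center: tuple[int, int, int] = (8, 8, 8)
    effect_radius_voxels: float = 3.0
    effect_size: float = 0.0
    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    smooth_fwhm_mm: float = 6.0
    ar1: float = 0.0
    base_amplitude: float = 0.5
    amplitude_sd: float = 0.15
    global_amplitude: float = 0.3
    global_amplitude_sd: float = 0.1
    age_mean: float = 22.0
    age_sd: float = 7.0
    n_sites: int = 2
    meanfd_median_mm: float = 0.08
    meanfd_log_sd: float = 0.5
    confound_group_meanfd: float = 0.0
    group_labels: tuple[str, str] = ("NT", "ASD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.n_timepoints < 32:
            raise ValueError("n_timepoints must be >= 32")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.effect_metric not in METRIC_NAMES:
            raise ValueError(
                f"effect_metric must be one of {METRIC_NAMES}, got "
                f"{self.effect_metric!r}"
            )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = -0.5 * (np.array(self.shape) - 1) * np.array(self.voxel_size_mm)
        return aff


@dataclass
class CohortDataset:
    """Per-subject 4D series + phenotype table + grid template."""

    timeseries: list[np.ndarray]
    phenotype: pd.DataFrame
    template: MaskedVolume
    tr_seconds: float
    effect_mask: np.ndarray
    spec: CohortSpec

    @property
    def n_subjects(self) -> int:
        return len(self.timeseries)


def _metric_config_for(spec: CohortSpec) -> MetricConfig:
    seed_mask = None
    if spec.effect_metric == "PCC_iFC":
        center = (np.array(spec.shape) - 1) / 2.0
        seed_mask = (tuple(center), 2.0)
    return MetricConfig(
        metric=spec.effect_metric,
        tr_seconds=spec.tr_seconds,
        smooth_fwhm_mm=spec.smooth_fwhm_mm,
        seed_mask=seed_mask,
    )


def _structured_signal(
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict:
    """Subject-independent pieces of the injected signal layout."""
    shape = tuple(spec.shape)
    region = _sphere(shape, spec.effect_center, spec.effect_radius_voxels)
    layout = {"region": region}
    if spec.effect_metric == "VMHC":
        layout["mirror"] = region[::-1, :, :]
    if spec.effect_metric == "PCC_iFC":
        center = (np.array(shape) - 1) / 2.0
        layout["seed"] = _sphere(shape, center, 2.0)
    if spec.effect_metric == "DC":
        # fixed scattered partner set the region couples to
        n_vox = int(np.prod(shape))
        partners = np.zeros(n_vox, dtype=bool)
        idx = rng.choice(n_vox, size=max(1, n_vox // 10), replace=False)
        partners[idx] = True
        layout["partners"] = partners.reshape(shape) & ~region
    return layout


def _subject_series(
    spec: CohortSpec,
    rng: np.random.Generator,
    layout: dict,
    alpha: float,
    gamma: float,
) -> np.ndarray:
    """One subject's 4D series: noise + global component + regional signal.

    ``alpha`` scales the regional (effect-carrying) signal; ``gamma``
    scales a brain-wide per-subject component that emulates global
    individual differences — it is what gives the within-mask map mean
    its between-subject variability (the role the map-mean nuisance
    covariate plays in the group GLM).
    """
    shape = tuple(spec.shape)
    n_t = spec.n_timepoints
    noise = rng.standard_normal(shape + (n_t,))
    if spec.ar1 != 0.0:
        from scipy.signal import lfilter

        noise = lfilter([1.0], [1.0, -spec.ar1], noise, axis=-1)
        noise /= np.sqrt(1.0 / (1.0 - spec.ar1**2))
    ts = noise

    metric = spec.effect_metric
    t = np.arange(n_t) * spec.tr_seconds
    if metric == "fALFF":
        phase = rng.uniform(0, 2 * np.pi)
        xi = np.sqrt(2.0) * np.sin(2 * np.pi * 0.05 * t + phase)
        phase_g = rng.uniform(0, 2 * np.pi)
        xi_global = np.sqrt(2.0) * np.sin(2 * np.pi * 0.03 * t + phase_g)
    else:
        xi = rng.standard_normal(n_t)
        xi_global = rng.standard_normal(n_t)

    ts += gamma * xi_global  # brain-wide
    region = layout["region"]
    ts[region] += alpha * xi
    if metric == "VMHC":
        ts[layout["mirror"]] += alpha * xi
    elif metric == "PCC_iFC":
        ts[layout["seed"]] += 1.0 * xi
    elif metric == "DC":
        ts[layout["partners"]] += 0.5 * xi
    return ts


def _cohort_maps(
    datasets: list[np.ndarray], template: MaskedVolume, cfg: MetricConfig
) -> np.ndarray:
    """(n_subjects, n_in_mask_voxels) matrix of derivative values."""
    rows = []
    for ts in datasets:
        dmap = compute_derivative(ts, template, cfg)
        rows.append(dmap.volume.data[template.mask])
    return np.array(rows)


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a two-group 4D cohort with a calibrated derivative effect.

    With ``effect_size = 0`` all subjects are exchangeable and the
    voxel-wise group GLM is null-calibrated by construction. With a
    non-zero effect size, a two-pass empirical calibration measures the
    within-group voxel-wise SD of the derivative in the effect region
    and the derivative-vs-amplitude slope on this cohort's own noise,
    then shifts the case group's signal amplitude to realize the
    requested standardized difference.
    """
    ss = np.random.SeedSequence(spec.seed)
    (layout_ss, pheno_ss, *subject_ss) = ss.spawn(2 + 2 * spec.n_per_group)
    layout = _structured_signal(spec, np.random.default_rng(layout_ss))

    n = 2 * spec.n_per_group
    template = MaskedVolume(
        np.zeros(spec.shape), spec.affine, np.ones(spec.shape, dtype=bool)
    )

    pheno_rng = np.random.default_rng(pheno_ss)
    group = np.repeat([0, 1], spec.n_per_group)
    age = pheno_rng.normal(spec.age_mean, spec.age_sd, n).clip(6, 80)
    site = pheno_rng.integers(0, spec.n_sites, n)
    meanfd = spec.meanfd_median_mm * np.exp(
        pheno_rng.normal(0.0, spec.meanfd_log_sd, n)
    )
    meanfd *= 1.0 + spec.confound_group_meanfd * group
    base_alpha = np.clip(
        spec.base_amplitude + spec.amplitude_sd * pheno_rng.standard_normal(n),
        0.0,
        None,
    )
    gammas = np.clip(
        spec.global_amplitude + spec.global_amplitude_sd * pheno_rng.standard_normal(n),
        0.0,
        None,
    )

    cfg = _metric_config_for(spec)
    delta = 0.0
    if spec.effect_size != 0.0:
        delta = _calibrate_amplitude_shift(
            spec, layout, template, cfg, base_alpha, gammas, subject_ss
        )
    alphas = base_alpha + delta * group

    series = [
        _subject_series(spec, np.random.default_rng(s), layout, a, g)
        for s, a, g in zip(subject_ss, alphas, gammas)
    ]

    pheno = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": [spec.group_labels[g] for g in group],
            "age": age,
            "site": [f"site{j}" for j in site],
            "mean_fd": meanfd,
        }
    )
    return CohortDataset(
        timeseries=series,
        phenotype=pheno,
        template=template,
        tr_seconds=spec.tr_seconds,
        effect_mask=layout["region"],
        spec=spec,
    )


def _calibrate_amplitude_shift(
    spec, layout, template, cfg, base_alpha, gammas, subject_ss
) -> float:
    """Solve for the case-group amplitude shift realizing effect_size.

    Uses the same per-subject noise streams as the final data, so the
    calibration sees exactly the variability the GLM will see.
    """
    region = layout["region"] & template.mask
    probe = 0.25 * max(spec.base_amplitude, 0.2)

    def region_matrix(alphas):
        series = [
            _subject_series(spec, np.random.default_rng(s), layout, a, g)
            for s, a, g in zip(subject_ss, alphas, gammas)
        ]
        maps = _cohort_maps(series, template, cfg)
        flat_region = region[template.mask]
        return maps[:, flat_region]

    vals0 = region_matrix(base_alpha)
    vals1 = region_matrix(base_alpha + probe)
    sd_vox = float(vals0.std(axis=0, ddof=1).mean())
    slope = float((vals1 - vals0).mean() / probe)
    if not np.isfinite(slope) or abs(slope) < 1e-12:
        raise RuntimeError(
            f"cannot calibrate {spec.effect_metric} effect: derivative does "
            "not respond to the injected signal"
        )
    return spec.effect_size * sd_vox / slope


def cohort_derivative_maps(ds: CohortDataset, cfg: MetricConfig | None = None):
    """Per-subject DerivativeMaps for the cohort's configured metric."""
    if cfg is None:
        cfg = _metric_config_for(ds.spec)
    return [
        compute_derivative(ts, ds.template, cfg, subject_id=sid)
        for ts, sid in zip(ds.timeseries, ds.phenotype["subject_id"])
    ]


# --------------------------------------------------------------------------
# synthetic parcellations


def make_synthetic_atlas(
    mask_or_shape,
    n_labels: int,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> MaskedVolume:
    """Partition a mask into ``n_labels`` connected labeled regions.

    Voronoi tessellation around randomly chosen in-mask seed voxels;
    stray disconnected fragments are merged into an adjacent label so
    every label region ends up connected (26-connectivity). Stand-in for
    published network parcellations.
    """
    if isinstance(mask_or_shape, MaskedVolume):
        mask = mask_or_shape.mask
        affine = mask_or_shape.affine if affine is None else affine
    elif isinstance(mask_or_shape, np.ndarray) and mask_or_shape.dtype == bool:
        mask = mask_or_shape
    else:
        mask = np.ones(tuple(mask_or_shape), dtype=bool)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    n_in = int(mask.sum())
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    if n_labels > n_in:
        raise ValueError(f"n_labels={n_labels} exceeds {n_in} in-mask voxels")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coords = np.argwhere(mask)
    chosen = coords[rng.choice(len(coords), size=n_labels, replace=False)]

    markers = np.zeros(mask.shape, dtype=bool)
    markers[tuple(chosen.T)] = True
    _, idx = ndimage.distance_transform_edt(~markers, return_indices=True)
    seed_label = np.zeros(mask.shape, dtype=np.int32)
    for lbl, c in enumerate(chosen, start=1):
        seed_label[tuple(c)] = lbl
    labels = seed_label[idx[0], idx[1], idx[2]]
    labels = np.where(mask, labels, 0)

    labels = _repair_connectivity(labels, mask)
    return MaskedVolume(labels.astype(float), affine, mask)


def _repair_connectivity(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reassign disconnected fragments to a touching neighbor label."""
    struct = np.ones((3, 3, 3), dtype=bool)
    for _ in range(20):
        changed = False
        for lbl in np.unique(labels[mask]):
            comp, n_comp = ndimage.label(labels == lbl, structure=struct)
            if n_comp <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n_comp + 1):
                if c == keep:
                    continue
                frag = comp == c
                ring = ndimage.binary_dilation(frag, structure=struct) & mask & ~frag
                neighbor_labels = labels[ring]
                neighbor_labels = neighbor_labels[neighbor_labels != lbl]
                if len(neighbor_labels):
                    vals, counts = np.unique(neighbor_labels, return_counts=True)
                    labels[frag] = vals[np.argmax(counts)]
                    changed = True
        if not changed:
            break
    return labels


# --------------------------------------------------------------------------
# on-disk outputs


def write_pair(pair: ZMapPair, out_dir, stem: str = "pair") -> dict:
    """Write a Z-map pair as NIfTI + JSON sidecar (spec, ground truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map_a": str(write_volume(pair.map_a, out_dir / f"{stem}_mapA.nii.gz")),
        "map_b": str(write_volume(pair.map_b, out_dir / f"{stem}_mapB.nii.gz")),
        "mask": str(
            write_mask(pair.shared_mask, pair.map_a.affine, out_dir / f"{stem}_mask.nii.gz")
        ),
    }
    sidecar = {
        "a_positive": pair.a_positive,
        "b_positive": pair.b_positive,
        "ground_truth": [
            {k: (np.argwhere(v).tolist() if k == "voxels" else _jsonable(v))
             for k, v in g.items()}
            for g in pair.ground_truth
        ],
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = str(sidecar_path)
    return paths


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, tuple):
        return [_jsonable(x) for x in v]
    return v
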