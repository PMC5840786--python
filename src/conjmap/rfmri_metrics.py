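"""Voxel-wise resting-state fMRI derivatives from 4D time series.

Five metrics: regional homogeneity (ReHo, Kendall's coefficient of
concordance over a voxel neighborhood), voxel-mirrored homotopic
connectivity (VMHC), degree centrality (DC), fractional amplitude of
low-frequency fluctuations (fALFF), and seed-based intrinsic functional
connectivity (seed iFC, e.g. a posterior-cingulate seed). Correlational
metrics are stored Fisher-z transformed. Spatial smoothing is applied to
the computed maps, never to the input series (smoothing input series
would inflate ReHo's local concordance).

A linear trend is removed before spectral and correlation metrics; ReHo
operates on ranks of the raw series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volume_io import MaskedVolume

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "DerivativeMap",
    "METRIC_NAMES",
    "reho",
    "vmhc",
    "degree_centrality",
    "falff",
    "seed_ifc",
    "smooth_volume",
    "compute_derivative",
    "fisher_z",
]

METRIC_NAMES = ("ReHo", "VMHC", "DC", "fALFF", "PCC_iFC")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Fisher-z clip so r = ±1 stays finite
_R_CLIP = 1.0 - 1e-7


@dataclass
class MetricConfig:
    """Configuration for one derivative computation.

    Defaults that the underlying studies leave to convention are recorded
    here so they travel with every output map: DC threshold r = 0.25 in
    weighted mode, fALFF band 0.01-0.1 Hz, 6 mm FWHM smoothing of the
    computed map, 27-voxel ReHo neighborhood.
    """

    metric: str = "ReHo"
    tr_seconds: float = 2.0
    reho_neighborhood: int = 27
    dc_r_threshold: float = 0.25
    dc_mode: str = "weighted"
    dc_voxel_budget: int = 20000
    falff_band_hz: tuple[float, float] = (0.01, 0.1)
    seed_mask: object = None  # MaskedVolume, bool array, or (center_voxel, radius_vox)
    smooth_fwhm_mm: float = 6.0
    detrend_quadratic: bool = False

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"metric must be one of {METRIC_NAMES}, got {self.metric!r}")
        if self.reho_neighborhood not in (7, 19, 27):
            raise ValueError("reho_neighborhood must be 7, 19 or 27")
        if not (0.0 < self.dc_r_threshold < 1.0):
            raise ValueError("dc_r_threshold must lie in (0, 1)")
        if self.dc_mode not in ("binary", "weighted"):
            raise ValueError("dc_mode must be 'binary' or 'weighted'")
        lo, hi = self.falff_band_hz
        if not (0.0 <= lo < hi):
            raise ValueError("fALFF band must satisfy 0 <= low < high")


@dataclass
class DerivativeMap:
    """A computed derivative volume plus provenance.

    ``mean_within_mask`` is carried forward because the group GLM uses
    each subject's map mean as a nuisance covariate.
    """

    volume: MaskedVolume
    metric: str
    subject_id: str = ""
    config: MetricConfig | None = None
    mean_within_mask: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_within_mask = float(self.volume.values().mean())


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with |r| clipped just inside 1 so outputs stay finite."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _detrend(ts2d: np.ndarray, quadratic: bool = False) -> np.ndarray:
    """Remove mean + linear (optionally quadratic) trend along axis 1."""
    n = ts2d.shape[1]
    t = np.linspace(-1.0, 1.0, n)
    cols = [np.ones(n), t] + ([t * t] if quadratic else [])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, ts2d.T, rcond=None)
    return ts2d - (X @ beta).T


def _standardize_rows(ts2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-norm rows; returns (standardized, was_constant)."""
    centered = ts2d - ts2d.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    const = norm == 0
    norm[const] = 1.0
    return centered / norm[:, None], const


def _neighborhood_offsets(size: int) -> np.ndarray:
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    if size == 27:
        keep = offs
    elif size == 19:
        keep = [o for o in offs if sum(map(abs, o)) <= 2]
    else:  # 7: faces + center
        keep = [o for o in offs if sum(map(abs, o)) <= 1]
    return np.array(keep, dtype=int)


def _shift3d(arr: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Shift with zero fill so voxel v reads arr[v + off]."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, o in enumerate(off):
        if o == 0:
            continue
        if o > 0:
            src[ax] = slice(o, None)
            dst[ax] = slice(None, -o)
        else:
            src[ax] = slice(None, o)
            dst[ax] = slice(-o, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def reho(ts4d: np.ndarray, template: MaskedVolume, cfg: MetricConfig) -> DerivativeMap:
    """Regional homogeneity: Kendall's W over each voxel's neighborhood.

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j) with S the sum of squared
    deviations of the per-timepoint rank sums from their mean, m the
    number of in-mask neighborhood series (including the voxel itself),
    n the number of timepoints, and T_j = sum_groups (t^3 - t) the tie
    correction of series j. Constant series are rank-undefined; such
    voxels are set to 0 and counted in a log summary.
    """
    n = ts4d.shape[-1]
    if n < 8:
        raise ValueError(f"ReHo requires >= 8 timepoints, got {n}")
    mask = template.mask
    shape = ts4d.shape[:3]

    flat = ts4d[mask]  # (V, n)
    const = np.ptp(flat, axis=1) == 0
    ranks = stats.rankdata(flat, axis=1)  # average ranks, ties handled

    # tie correction per series
    tie = np.zeros(flat.shape[0])
    sorted_r = np.sort(ranks, axis=1)
    # run-lengths of equal ranks per row
    for i in np.nonzero((np.diff(sorted_r, axis=1) == 0).any(axis=1))[0]:
        _, counts = np.unique(sorted_r[i], return_counts=True)
        tie[i] = float(((counts**3) - counts).sum())

    rank_vol = np.zeros(shape + (n,))
    rank_vol[mask] = ranks
    tie_vol = np.zeros(shape)
    tie_vol[mask] = tie
    valid = (mask & ~_unflatten(const, mask, shape)).astype(float)
    rank_vol *= valid[..., None]
    tie_vol *= valid

    offsets = _neighborhood_offsets(cfg.reho_neighborhood)
    rank_sum = np.zeros(shape + (n,))
    tie_sum = np.zeros(shape)
    m_count = np.zeros(shape)
    for off in offsets:
        rank_sum += _shift3d(rank_vol, off)
        tie_sum += _shift3d(tie_vol, off)
        m_count += _shift3d(valid, off)

    m = m_count
    mean_rank_sum = m * (n + 1) / 2.0
    s = ((rank_sum - mean_rank_sum[..., None]) ** 2).sum(axis=-1)
    denom = m**2 * (n**3 - n) - m * tie_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / denom, 0.0)
    w = np.where(mask & (valid > 0), w, 0.0)
    n_const = int(const.sum())
    if n_const:
        logger.info("ReHo: %d constant in-mask series set to 0", n_const)
    vol = MaskedVolume(np.clip(w, 0.0, 1.0), template.affine, mask)
    return DerivativeMap(vol, "ReHo", config=cfg)


def _unflatten(flat: np.ndarray, mask: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=flat.dtype)
    out[mask] = flat
    return out


def vmhc(ts4d: np.ndarray, template: MaskedVolume, cfg: MetricConfig) -> DerivativeMap:
    """Voxel-mirrored homotopic connectivity.

    Pearson correlation between each voxel's (detrended) series and that
    of its left-right mirror across the first axis, Fisher-z transformed.
    Midline voxels of odd grids mirror onto themselves (r = 1 by
    construction). Voxels whose mirror lies outside the mask are excluded
    from the output mask.
    """
    mask = template.mask
    mirrored_mask = mask[::-1, :, :]
    out_mask = mask & mirrored_mask

    flat = _detrend(ts4d[out_mask], cfg.detrend_quadratic)
    std, const = _standardize_rows(flat)
    mirror_ts = ts4d[::-1, :, :, :][out_mask]
    mstd, mconst = _standardize_rows(_detrend(mirror_ts, cfg.detrend_quadratic))
    r = np.einsum("ij,ij->i", std, mstd)
    r[const | mconst] = 0.0
    z = fisher_z(r)
    vol = MaskedVolume(_unflatten(z, out_mask, mask.shape), template.affine, out_mask)
    return DerivativeMap(vol, "VMHC", config=cfg)


def degree_centrality(
    ts4d: np.ndarray, template: MaskedVolume, cfg: MetricConfig
) -> DerivativeMap:
    """Weighted or binary degree centrality over all in-mask voxel pairs.

    For each voxel: correlations with every other in-mask voxel; those
    exceeding ``dc_r_threshold`` contribute 1 (binary) or their Fisher-z
    value (weighted). Self-correlation is excluded. Above the voxel
    budget the full correlation matrix is never materialized; a chunked
    pass accumulates the same counts.
    """
    mask = template.mask
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise ValueError("degree centrality requires >= 2 in-mask voxels")
    flat = _detrend(ts4d[mask], cfg.detrend_quadratic)
    std, const = _standardize_rows(flat)

    if n_vox <= cfg.dc_voxel_budget:
        chunk = n_vox
    else:
        # cap the materialized block at ~2e7 correlations (~160 MB)
        chunk = max(1, int(2e7 // n_vox))
        logger.info(
            "DC: %d voxels exceeds budget %d; using chunked pass",
            n_vox,
            cfg.dc_voxel_budget,
        )
    out = np.zeros(n_vox)
    thr = cfg.dc_r_threshold
    for start in range(0, n_vox, chunk):
        stop = min(start + chunk, n_vox)
        r_block = std[start:stop] @ std.T
        # remove self-correlation
        idx = np.arange(start, stop)
        r_block[np.arange(stop - start), idx] = 0.0
        above = r_block > thr
        if cfg.dc_mode == "binary":
            out[start:stop] = above.sum(axis=1)
        else:
            out[start:stop] = np.where(above, fisher_z(r_block), 0.0).sum(axis=1)
    out[const] = 0.0
    vol = MaskedVolume(_unflatten(out, mask, mask.shape), template.affine, mask)
    return DerivativeMap(vol, "DC", config=cfg)


def falff(ts4d: np.ndarray, template: MaskedVolume, cfg: MetricConfig) -> DerivativeMap:
    """Fractional amplitude of low-frequency fluctuations.

    After linear detrending: sum of Fourier amplitudes over the band
    divided by the sum over all positive frequencies. Values in [0, 1].
    """
    if cfg.tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive for fALFF")
    nyquist = 0.5 / cfg.tr_seconds
    lo, hi = cfg.falff_band_hz
    if hi > nyquist:
        raise ValueError(
            f"fALFF band upper edge {hi} Hz exceeds Nyquist {nyquist:.4f} Hz"
        )
    mask = template.mask
    flat = _detrend(ts4d[mask], cfg.detrend_quadratic)
    n = flat.shape[1]
    amp = np.abs(np.fft.rfft(flat, axis=1))
    freqs = np.fft.rfftfreq(n, d=cfg.tr_seconds)
    pos = freqs > 0
    band = pos & (freqs >= lo) & (freqs <= hi)
    total = amp[:, pos].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, amp[:, band].sum(axis=1) / total, 0.0)
    vol = MaskedVolume(_unflatten(frac, mask, mask.shape), template.affine, mask)
    return DerivativeMap(vol, "fALFF", config=cfg)


def _resolve_seed_mask(cfg: MetricConfig, template: MaskedVolume) -> np.ndarray:
    seed = cfg.seed_mask
    if seed is None:
        raise ValueError("seed iFC requires cfg.seed_mask")
    if isinstance(seed, MaskedVolume):
        seed_arr = seed.mask
    elif isinstance(seed, tuple) and len(seed) == 2:
        center, radius = seed
        grids = np.indices(template.shape)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        seed_arr = d2 <= radius**2
    else:
        seed_arr = np.asarray(seed, dtype=bool)
    seed_arr = seed_arr & template.mask
    if not seed_arr.any():
        raise ValueError("seed mask is empty after intersecting the analysis mask")
    return seed_arr


def seed_ifc(
    ts4d: np.ndarray, template: MaskedVolume, cfg: MetricConfig
) -> DerivativeMap:
    """Seed-based iFC: per-voxel correlation with the mean seed series, Fisher-z."""
    mask = template.mask
    seed_arr = _resolve_seed_mask(cfg, template)
    seed_ts = ts4d[seed_arr].mean(axis=0)
    if np.ptp(seed_ts) == 0:
        raise ValueError("seed time series is constant; correlation undefined")
    seed_std, _ = _standardize_rows(_detrend(seed_ts[None, :], cfg.detrend_quadratic))
    flat = _detrend(ts4d[mask], cfg.detrend_quadratic)
    std, const = _standardize_rows(flat)
    r = std @ seed_std[0]
    r[const] = 0.0
    vol = MaskedVolume(_unflatten(fisher_z(r), mask, mask.shape), template.affine, mask)
    return DerivativeMap(vol, "PCC_iFC", config=cfg)


def smooth_volume(vol: MaskedVolume, fwhm_mm: float) -> MaskedVolume:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis in mm.

    The mask is re-applied afterwards; out-of-mask voxels enter the
    convolution as zeros, so near mask edges values shrink toward zero
    (interior statistics are unaffected).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vol.voxel_size_mm
    data = ndimage.gaussian_filter(np.where(vol.mask, vol.data, 0.0), sigma_vox)
    return vol.with_data(np.where(vol.mask, data, 0.0))


_METRIC_FUNCS = {
    "ReHo": reho,
    "VMHC": vmhc,
    "DC": degree_centrality,
    "fALFF": falff,
    "PCC_iFC": seed_ifc,
}


def compute_derivative(
    ts4d: np.ndarray,
    template: MaskedVolume,
    cfg: MetricConfig,
    subject_id: str = "",
    smooth: bool = True,
) -> DerivativeMap:
    """Compute the configured metric, then smooth the map by cfg.smooth_fwhm_mm."""
    dmap = _METRIC_FUNCS[cfg.metric](ts4d, template, cfg)
    if smooth and cfg.smooth_fwhm_mm > 0:
        dmap = DerivativeMap(
            smooth_volume(dmap.volume, cfg.smooth_fwhm_mm),
            dmap.metric,
            subject_id=subject_id,
            config=cfg,
        )
    else:
        dmap.subject_id = subject_id
    return dmap
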