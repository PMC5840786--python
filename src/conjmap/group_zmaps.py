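"""Voxel-wise group-contrast Z-maps from per-subject derivative maps.

One ordinary-least-squares GLM per voxel with the group indicator as the
regressor of interest and age (centered), site (reference-coded fixed
dummies), mean framewise displacement, and each subject's within-mask
derivative mean as nuisance covariates. The group t statistic is
converted to a Z value by matching cumulative probabilities of the
t(residual df) and standard normal distributions, computed in log space
so extreme tails stay finite at printed precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .rfmri_metrics import DerivativeMap
from .volume_io import MaskedVolume, check_grid_compatible, intersect_masks

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastZMap",
    "validate_phenotype",
    "build_design_matrix",
    "fit_voxelwise_glm",
    "t_to_z",
]

REQUIRED_COLUMNS = ("subject_id", "group", "age", "site", "mean_fd")


@dataclass
class ContrastZMap:
    """Signed Z-map for a group contrast plus design provenance."""

    volume: MaskedVolume
    positive_direction: str  # e.g. "ASD>NT" or "M>F"
    n_per_group: dict
    design_columns: list[str] = field(default_factory=list)
    residual_df: int = 0


def validate_phenotype(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check ids unique, both group levels present, no missing covariates."""
    missing = [c for c in REQUIRED_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if pheno["subject_id"].duplicated().any():
        dup = pheno.loc[pheno["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dup}")
    levels = pheno["group"].unique()
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {list(levels)}")
    covar = pheno[list(REQUIRED_COLUMNS)]
    if covar.isna().any().any():
        bad = covar.columns[covar.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns: {bad}")
    return pheno


def build_design_matrix(
    pheno: pd.DataFrame,
    positive_group: str | None = None,
    derivative_means: np.ndarray | None = None,
) -> tuple[pd.DataFrame, str]:
    """Design: intercept, group, age_c, site dummies, mean_fd, derivative_mean.

    The group indicator codes ``positive_group`` as 1; the default is the
    lexicographically later level, so pass it explicitly when the contrast
    direction matters (e.g. positive_group="ASD" for an ASD>NT map). Site is
    reference-coded against its first level; a single site contributes no
    dummy columns. Rank deficiency raises with the offending columns named.
    """
    pheno = validate_phenotype(pheno)
    levels = sorted(pheno["group"].unique())
    if positive_group is None:
        positive_group = levels[-1]
    if positive_group not in levels:
        raise ValueError(f"positive_group {positive_group!r} not in {levels}")

    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(pheno)),
        "group": (pheno["group"] == positive_group).to_numpy(float),
        "age_c": (pheno["age"] - pheno["age"].mean()).to_numpy(float),
    }
    site_levels = sorted(pheno["site"].unique())
    for lvl, count in pheno["site"].value_counts().items():
        if count < 2:
            logger.warning("site %r has only %d subject(s)", lvl, count)
    for lvl in site_levels[1:]:
        cols[f"site_{lvl}"] = (pheno["site"] == lvl).to_numpy(float)
    cols["mean_fd"] = pheno["mean_fd"].to_numpy(float)
    if derivative_means is not None:
        cols["derivative_mean"] = np.asarray(derivative_means, dtype=float)
    elif "derivative_mean" in pheno.columns:
        cols["derivative_mean"] = pheno["derivative_mean"].to_numpy(float)

    X = pd.DataFrame(cols, index=pheno.index)
    _check_full_rank(X)
    return X, positive_group


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # name columns predictable from the others
    collinear = []
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ proj
        scale = np.linalg.norm(arr[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-8:
            collinear.append(name)
    raise ValueError(
        f"design matrix is rank-deficient (rank {rank} < {arr.shape[1]}); "
        f"collinear columns: {collinear}"
    )


def t_to_z(t, df: float):
    """Probability-matching t -> Z transform (sign-preserving, monotone).

    Z solves Phi(Z) = F_t(t, df) via log-space survival functions, so
    very large |t| maps to finite Z instead of overflowing.
    """
    if df < 1:
        raise ValueError("t_to_z requires df >= 1")
    t_arr = np.asarray(t, dtype=float)
    out = np.full(t_arr.shape, np.nan)
    finite = np.isfinite(t_arr)
    tt = t_arr[finite]
    # work on |t| in the upper tail, restore sign after
    log_sf = stats.t.logsf(np.abs(tt), df)
    z_mag = -special.ndtri_exp(log_sf)
    out[finite] = np.sign(tt) * z_mag
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def fit_voxelwise_glm(
    maps: list[DerivativeMap],
    pheno: pd.DataFrame,
    positive_group: str | None = None,
    mask: np.ndarray | None = None,
) -> ContrastZMap:
    """OLS per voxel; Z-map for the group coefficient.

    Maps must be grid-compatible and row-aligned with the phenotype
    table. The fit runs within the intersection of all subject masks
    (and ``mask`` if given). Voxels with zero residual variance get
    Z = 0 and are counted in a log message.
    """
    if len(maps) != len(pheno):
        raise ValueError(
            f"{len(maps)} maps but {len(pheno)} phenotype rows"
        )
    ref = maps[0].volume
    for m in maps[1:]:
        if not check_grid_compatible(ref, m.volume):
            raise ValueError("derivative maps are not grid-compatible")
    all_masks = [m.volume.mask for m in maps] + ([mask] if mask is not None else [])
    fit_mask = intersect_masks(all_masks)

    X_df, positive_group = build_design_matrix(
        pheno,
        positive_group=positive_group,
        derivative_means=np.array([m.mean_within_mask for m in maps]),
    )
    X = X_df.to_numpy()
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"non-positive residual df ({n} subjects, {p} columns)")

    Y = np.stack([m.volume.data[fit_mask] for m in maps])  # (n, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df

    j = list(X_df.columns).index("group")
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    # relative tolerance: exact-fit voxels leave only rounding error behind
    zero_var = sigma2 <= 1e-20 * np.maximum(1.0, (Y**2).mean(axis=0))
    if zero_var.any():
        logger.info("GLM: %d voxels with zero residual variance set to Z=0", int(zero_var.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(zero_var, 0.0, beta[j] / np.where(zero_var, 1.0, se))
    z_vals = t_to_z(t_vals, df)

    data = np.zeros(ref.shape)
    data[fit_mask] = z_vals
    groups = pheno["group"].value_counts().to_dict()
    neg = [g for g in groups if g != positive_group][0]
    return ContrastZMap(
        volume=MaskedVolume(data, ref.affine, fit_mask),
        positive_direction=f"{positive_group}>{neg}",
        n_per_group=groups,
        design_columns=list(X_df.columns),
        residual_df=df,
    )
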