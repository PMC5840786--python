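"""NIfTI volume I/O, grid-compatibility checks, and analysis-mask construction.

All statistics downstream are computed strictly within a boolean analysis
mask carried alongside each volume. Voxel coordinates are 0-based array
indices; world coordinates follow the NIfTI affine (RAS+). No implicit
resampling is ever performed: grids must match exactly, because silent
interpolation would corrupt the overlap statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MaskedVolume",
    "read_volume",
    "read_timeseries",
    "write_volume",
    "write_mask",
    "check_grid_compatible",
    "intersect_masks",
]


@dataclass
class MaskedVolume:
    """A 3D scalar field on a voxel grid with affine and analysis mask.

    Parameters
    ----------
    data : 3D float array
    affine : 4x4 voxel-to-world matrix (RAS+ mm)
    mask : 3D boolean array, same shape as ``data``; statistics are
        computed within the mask only. Defaults to all-true.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 + 1:
            raise ValueError(
                f"MaskedVolume requires a 3D array, got {self.data.ndim}D"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.voxel_size_mm)) or np.any(
            self.voxel_size_mm <= 0
        ):
            raise ValueError(f"invalid voxel sizes {self.voxel_size_mm}")
        # NaN voxels are an artifact of masked uploads: treat as outside-mask.
        bad = ~np.isfinite(self.data)
        if bad.any():
            n = int((bad & self.mask).sum())
            if n:
                logger.warning("%d non-finite in-mask voxels moved outside mask", n)
            self.mask &= ~bad
            self.data = np.where(bad, 0.0, self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def values(self) -> np.ndarray:
        """Flat array of in-mask voxel values."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "MaskedVolume":
        """New volume on the same grid/mask with different data."""
        return MaskedVolume(data, self.affine.copy(), self.mask.copy())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n x 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    return img


def read_volume(path, mask: np.ndarray | None = None) -> MaskedVolume:
    """Read a 3D NIfTI volume.

    Non-finite voxels are excluded from the mask. A 4D file is rejected
    with a pointer to :func:`read_timeseries`.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim == 4:
        raise ValueError(
            f"{path} is 4D; use read_timeseries() for 4D time-series volumes"
        )
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return MaskedVolume(data.astype(np.float64), img.affine, mask)


def read_timeseries(path) -> tuple[np.ndarray, MaskedVolume, float]:
    """Read a 4D NIfTI; returns (ts4d, template volume, TR seconds).

    The template carries the grid and an all-finite mask; TR is taken from
    the header pixdim[4] (0.0 if absent).
    """
    img = _load_nifti(path)
    ts = np.asanyarray(img.dataobj).astype(np.float64)
    if ts.ndim != 4:
        raise ValueError(f"{path}: expected a 4D time series, got {ts.ndim}D")
    finite = np.isfinite(ts).all(axis=-1)
    template = MaskedVolume(ts[..., 0], img.affine, finite)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    return ts, template, tr


def write_volume(vol: MaskedVolume, path) -> Path:
    """Write a volume as float32 NIfTI-1 (out-of-mask voxels zeroed)."""
    path = Path(path)
    data = np.where(vol.mask, vol.data, 0.0).astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.to_filename(str(path))
    return path


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a boolean mask as uint8 NIfTI-1."""
    path = Path(path)
    nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine).to_filename(str(path))
    return path


def check_grid_compatible(a: MaskedVolume, b: MaskedVolume, atol: float = 1e-4) -> bool:
    """True iff shapes are equal and affines agree within ``atol``."""
    return a.shape == b.shape and bool(
        np.allclose(a.affine, b.affine, atol=atol, rtol=0.0)
    )


def require_compatible(a: MaskedVolume, b: MaskedVolume) -> None:
    if not check_grid_compatible(a, b):
        raise ValueError(
            "volumes are not grid-compatible "
            f"(shapes {a.shape} vs {b.shape}; affines may differ)"
        )


def intersect_masks(masks: list) -> np.ndarray:
    """Logical AND of masks on a common grid.

    Accepts boolean arrays or MaskedVolumes (whose ``mask`` is used).
    Raises on an empty list or an empty intersection; the error names the
    first mask whose inclusion empties the running intersection.
    """
    if len(masks) == 0:
        raise ValueError("intersect_masks requires at least one mask")
    arrays = [
        (m.mask if isinstance(m, MaskedVolume) else np.asarray(m, dtype=bool))
        for m in masks
    ]
    shape = arrays[0].shape
    for i, m in enumerate(arrays):
        if m.shape != shape:
            raise ValueError(f"mask {i} shape {m.shape} != {shape}")
    out = arrays[0].copy()
    for i, m in enumerate(arrays[1:], start=1):
        out &= m
        if not out.any():
            raise ValueError(
                f"mask intersection became empty after including mask {i}"
            )
    if not out.any():
        raise ValueError("mask intersection is empty")
    return out
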