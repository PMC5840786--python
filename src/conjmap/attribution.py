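"""Characterize conjunction masks against parcellations and ontology maps.

Network attribution follows the histogram convention: percentages are
taken over the atlas-covered part of the mask (voxels the parcellation
does not cover are reported separately as unassigned), so the per-label
percentages partition to 100. Ontology components are probabilistic and
may overlap, so their percentages are each over the whole mask and need
not sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import MaskedVolume, check_grid_compatible

__all__ = [
    "AtlasVolume",
    "OntologyMaps",
    "network_attribution",
    "ontology_attribution",
    "characterize_clusters",
]


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation with label names (e.g. 7 networks)."""

    volume: MaskedVolume
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.labels
        if (labels < 0).any():
            raise ValueError("atlas labels must be positive integers (0 = unlabeled)")
        present = set(np.unique(labels[labels > 0]).tolist())
        missing = present - set(self.names)
        if self.names and missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if not self.names:
            self.names = {int(l): f"label{int(l)}" for l in sorted(present)}

    @property
    def labels(self) -> np.ndarray:
        return np.round(self.volume.data).astype(int) * self.volume.mask


@dataclass
class OntologyMaps:
    """Probabilistic component maps (C1..CK) with a probability threshold."""

    maps: list[MaskedVolume]
    labels: list[str] = field(default_factory=list)
    probability_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("probability_threshold must lie in (0, 1)")
        for i, m in enumerate(self.maps):
            vals = m.values()
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"component {i}: probabilities outside [0, 1]")
        if not self.labels:
            self.labels = [f"C{i + 1}" for i in range(len(self.maps))]
        if len(self.labels) != len(self.maps):
            raise ValueError("labels and maps length mismatch")


def network_attribution(mask: np.ndarray, atlas: AtlasVolume) -> pd.DataFrame:
    """Percent of mask voxels per atlas label, over atlas-covered voxels.

    Returns a table with one row per label (plus an ``unassigned`` row
    giving the percent of mask voxels the atlas does not cover, relative
    to the whole mask). Label percentages sum to 100 whenever any mask
    voxel is covered.
    """
    if mask.shape != atlas.volume.shape:
        raise ValueError("mask and atlas grids differ")
    if not mask.any():
        raise ValueError("attribution of an empty mask is undefined")
    labels = atlas.labels
    covered = mask & (labels > 0)
    n_cov = int(covered.sum())
    rows = []
    for lbl, name in sorted(atlas.names.items()):
        n = int((covered & (labels == lbl)).sum())
        pct = 100.0 * n / n_cov if n_cov else 0.0
        rows.append({"label": lbl, "name": name, "n_voxels": n, "percent": pct})
    n_un = int(mask.sum()) - n_cov
    rows.append(
        {
            "label": 0,
            "name": "unassigned",
            "n_voxels": n_un,
            "percent": 100.0 * n_un / int(mask.sum()),
        }
    )
    return pd.DataFrame(rows)


def ontology_attribution(mask: np.ndarray, maps: OntologyMaps) -> pd.DataFrame:
    """Percent of mask voxels inside each thresholded component map."""
    if not mask.any():
        raise ValueError("attribution of an empty mask is undefined")
    n_mask = int(mask.sum())
    rows = []
    for name, comp in zip(maps.labels, maps.maps):
        if comp.shape != mask.shape:
            raise ValueError(f"component {name}: grid mismatch")
        inside = mask & (comp.data >= maps.probability_threshold) & comp.mask
        rows.append(
            {
                "component": name,
                "n_voxels": int(inside.sum()),
                "percent": 100.0 * int(inside.sum()) / n_mask,
            }
        )
    return pd.DataFrame(rows)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def characterize_clusters(
    mask: np.ndarray,
    template: MaskedVolume,
    zmap: MaskedVolume | None = None,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Connected components of a mask: size, volume, peak Z, center of mass.

    Centers of mass and peak locations are in world (mm) coordinates via
    the template affine. Empty mask -> empty table.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if zmap is not None and not check_grid_compatible(template, zmap):
        raise ValueError("zmap grid differs from template")
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    rows = []
    vox_mm3 = template.voxel_volume_mm3
    for lbl in range(1, n + 1):
        comp = labeled == lbl
        size = int(comp.sum())
        com_vox = np.array(ndimage.center_of_mass(comp))
        com_mm = template.voxel_to_world(com_vox)[0]
        row = {
            "cluster": lbl,
            "n_voxels": size,
            "volume_mm3": size * vox_mm3,
            "com_x_mm": com_mm[0],
            "com_y_mm": com_mm[1],
            "com_z_mm": com_mm[2],
        }
        if zmap is not None:
            vals = np.where(comp, np.abs(zmap.data), -np.inf)
            peak_idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
            row["peak_z"] = float(zmap.data[peak_idx])
            peak_mm = template.voxel_to_world(np.array(peak_idx, float))[0]
            row["peak_x_mm"] = peak_mm[0]
            row["peak_y_mm"] = peak_mm[1]
            row["peak_z_mm"] = peak_mm[2]
        rows.append(row)
    rows.sort(key=lambda r: -r["n_voxels"])
    for i, r in enumerate(rows, start=1):
        r["cluster"] = i
    return pd.DataFrame(rows)
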