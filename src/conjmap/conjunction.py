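"""Directional multi-threshold conjunction of two signed Z-maps.

The statistic: threshold two group-difference Z-maps at a dense grid of
voxel-level p cutoffs (default 500 thresholds, p < 0.05 down to
p < 0.0001 in steps of 0.0001), AND the two directional suprathreshold
masks, and summarize the overlap at each threshold as the mean of the two
per-map intersection proportions. Four directional scenarios arise from
crossing the two contrast directions: with map A the case-control
contrast (positive = cases higher) and map B the sex contrast (positive =
males higher),

    EMB1: A+ and B+   (shift-towards-maleness, increases)
    EMB2: A- and B-   (shift-towards-maleness, decreases)
    GI1:  A+ and B-   (shift-towards-femaleness, increases)
    GI2:  A- and B+   (shift-towards-femaleness, decreases)

No cluster-extent filtering is applied anywhere in the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volume_io import MaskedVolume, check_grid_compatible, intersect_masks

__all__ = [
    "ThresholdGrid",
    "ScenarioSpec",
    "SCENARIOS",
    "SCENARIO_NAMES",
    "ZMapPair",
    "OverlapCurve",
    "build_threshold_grid",
    "p_to_z_one_tailed",
    "directional_suprathreshold",
    "overlap_percentage",
    "scenario_overlap_curves",
    "conjunction_mask",
]

#: display threshold used for reporting conjunction masks (one-tailed p≈0.005)
DISPLAY_Z = 2.58


@dataclass(frozen=True)
class ThresholdGrid:
    """Descending voxel-level p thresholds with matched one-tailed Z cutoffs."""

    p_values: np.ndarray
    z_values: np.ndarray
    tail: str = "one_tailed"

    def __len__(self) -> int:
        return len(self.p_values)


def p_to_z_one_tailed(p) -> np.ndarray | float:
    """Upper-tail standard normal quantile for p in (0,1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie strictly within (0, 1)")
    z = stats.norm.isf(p_arr)
    return float(z) if np.isscalar(p) or z.ndim == 0 else z


def build_threshold_grid(
    p_start: float = 0.05,
    p_end: float = 0.0001,
    step: float = 0.0001,
    tail: str = "one_tailed",
) -> ThresholdGrid:
    """Build the descending multi-threshold grid.

    Defaults give exactly 500 thresholds from p < 0.05 to p < 0.0001
    decrementing by 0.0001. The span must be an integer multiple of the
    step. ``tail='two_tailed'`` converts each p as p/2 per tail.
    """
    if not (0.0 < p_end <= p_start < 1.0):
        raise ValueError("need 0 < p_end <= p_start < 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n_float = (p_start - p_end) / step
    n_round = round(n_float)
    if abs(n_float - n_round) > 1e-6:
        raise ValueError(
            f"(p_start - p_end) = {p_start - p_end:g} is not an integer "
            f"multiple of step {step:g}"
        )
    p = p_start - step * np.arange(n_round + 1)
    if tail == "one_tailed":
        z = stats.norm.isf(p)
    elif tail == "two_tailed":
        z = stats.norm.isf(p / 2.0)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return ThresholdGrid(p_values=p, z_values=z, tail=tail)


@dataclass(frozen=True)
class ScenarioSpec:
    """One directional overlap scenario.

    ``a_sign``/``b_sign`` are +1/-1: the sign of the suprathreshold tail
    taken on the case-control map (A) and the sex-difference map (B).
    """

    name: str
    a_sign: int
    b_sign: int
    model: str  # "EMB" (shift-towards-maleness) or "GI" (shift-towards-femaleness)

    @property
    def a_direction(self) -> str:
        return "greater" if self.a_sign > 0 else "less"

    @property
    def b_direction(self) -> str:
        return "greater" if self.b_sign > 0 else "less"


SCENARIOS: dict[str, ScenarioSpec] = {
    "EMB1": ScenarioSpec("EMB1", +1, +1, "EMB"),
    "EMB2": ScenarioSpec("EMB2", -1, -1, "EMB"),
    "GI1": ScenarioSpec("GI1", +1, -1, "GI"),
    "GI2": ScenarioSpec("GI2", -1, +1, "GI"),
}
SCENARIO_NAMES = tuple(SCENARIOS)


@dataclass
class ZMapPair:
    """Two signed Z-maps on a common grid with contrast-direction metadata.

    ``a_positive``/``b_positive`` document which group is the positive
    direction of each contrast (e.g. "ASD>NT", "M>F"). The shared analysis
    mask is the intersection of the two input masks.
    """

    map_a: MaskedVolume
    map_b: MaskedVolume
    a_positive: str = "ASD>NT"
    b_positive: str = "M>F"
    ground_truth: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not check_grid_compatible(self.map_a, self.map_b):
            raise ValueError("Z-map pair is not grid-compatible")
        self.shared_mask = intersect_masks([self.map_a.mask, self.map_b.mask])


@dataclass
class OverlapCurve:
    """Per-threshold overlap percentages for one scenario."""

    scenario: ScenarioSpec
    grid: ThresholdGrid
    overlap_percent: np.ndarray
    count_a: np.ndarray
    count_b: np.ndarray
    count_intersection: np.ndarray


def directional_suprathreshold(
    vol: MaskedVolume, direction: str, z_cut: float, shared_mask: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of voxels beyond ``z_cut`` in the given direction.

    ``direction='greater'`` selects Z >= +z_cut, ``'less'`` selects
    Z <= -z_cut, within the analysis mask (optionally further restricted
    to a shared mask).
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive; direction carries the sign")
    if direction == "greater":
        out = vol.data >= z_cut
    elif direction == "less":
        out = vol.data <= -z_cut
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    out &= vol.mask
    if shared_mask is not None:
        out &= shared_mask
    return out


def overlap_percentage(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mean of the two per-map intersection proportions, as a percent.

    100 * 0.5 * (|A∩B|/|A| + |A∩B|/|B|); defined as 0 when either mask
    is empty. Symmetric in A and B.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a grid")
    na = int(mask_a.sum())
    nb = int(mask_b.sum())
    if na == 0 or nb == 0:
        return 0.0
    ni = int((mask_a & mask_b).sum())
    return 100.0 * 0.5 * (ni / na + ni / nb)


def _tail_values(values: np.ndarray, sign: int) -> np.ndarray:
    """Signed values folded so that the requested tail is the upper tail."""
    return values if sign > 0 else -values


def overlap_curve_from_values(
    a: np.ndarray, b: np.ndarray, z_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Overlap percentages over a cutoff grid from flat in-mask values.

    Counts |{a >= z}|, |{b >= z}| and |{min(a,b) >= z}| for every cutoff
    via sorted arrays; equivalent to looping thresholds over boolean masks
    but O((n + T) log n).
    """
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    m_sorted = np.sort(np.minimum(a, b))
    n = a.size
    ca = n - np.searchsorted(a_sorted, z_values, side="left")
    cb = n - np.searchsorted(b_sorted, z_values, side="left")
    ci = n - np.searchsorted(m_sorted, z_values, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * 0.5 * (ci / ca + ci / cb)
    pct = np.where((ca == 0) | (cb == 0), 0.0, pct)
    return pct, ca, cb, ci


def scenario_overlap_curves(
    pair: ZMapPair, grid: ThresholdGrid
) -> dict[str, OverlapCurve]:
    """Overlap curves for all four directional scenarios.

    Deterministic: no randomness enters this module.
    """
    a = pair.map_a.data[pair.shared_mask]
    b = pair.map_b.data[pair.shared_mask]
    out: dict[str, OverlapCurve] = {}
    for name, spec in SCENARIOS.items():
        pct, ca, cb, ci = overlap_curve_from_values(
            _tail_values(a, spec.a_sign), _tail_values(b, spec.b_sign), grid.z_values
        )
        out[name] = OverlapCurve(
            scenario=spec,
            grid=grid,
            overlap_percent=pct,
            count_a=ca,
            count_b=cb,
            count_intersection=ci,
        )
    return out


def conjunction_mask(
    pair: ZMapPair, scenario: ScenarioSpec | str, z_cut: float = DISPLAY_Z
) -> np.ndarray:
    """AND-mask of the two directional suprathreshold sets at ``z_cut``."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    ma = directional_suprathreshold(
        pair.map_a, scenario.a_direction, z_cut, pair.shared_mask
    )
    mb = directional_suprathreshold(
        pair.map_b, scenario.b_direction, z_cut, pair.shared_mask
    )
    return ma & mb
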