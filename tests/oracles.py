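"""Independent brute-force oracle implementations used only by tests.

Every function here is a deliberately naive explicit-loop computation of
a quantity the package computes by a vectorized or sorted-array path.
They share no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for an (m, n) series matrix."""
    m, n = series.shape
    ranks = np.array([stats.rankdata(s) for s in series])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_total = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_total += float(((counts**3) - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_total
    return 12.0 * s / denom if denom > 0 else 0.0


def brute_reho(ts4d: np.ndarray, mask: np.ndarray, offsets) -> np.ndarray:
    """Voxel-by-voxel ReHo via explicit neighborhood loops."""
    shape = ts4d.shape[:3]
    out = np.zeros(shape)
    for idx in np.argwhere(mask):
        if np.ptp(ts4d[tuple(idx)]) == 0:
            continue
        neigh = []
        for off in offsets:
            j = idx + np.array(off)
            if np.all(j >= 0) and np.all(j < shape) and mask[tuple(j)]:
                if np.ptp(ts4d[tuple(j)]) > 0:
                    neigh.append(ts4d[tuple(j)])
        out[tuple(idx)] = brute_kendall_w(np.array(neigh))
    return out


def brute_vmhc(ts4d: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mirror correlations (Fisher-z) by per-voxel np.corrcoef calls."""
    shape = ts4d.shape[:3]
    out = np.zeros(shape)
    out_mask = np.zeros(shape, dtype=bool)
    nx = shape[0]
    for idx in np.argwhere(mask):
        mi = (nx - 1 - idx[0], idx[1], idx[2])
        if not mask[mi]:
            continue
        a = _detrend1(ts4d[tuple(idx)])
        b = _detrend1(ts4d[mi])
        r = np.corrcoef(a, b)[0, 1]
        out[tuple(idx)] = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))
        out_mask[tuple(idx)] = True
    return out, out_mask


def _detrend1(x: np.ndarray) -> np.ndarray:
    n = len(x)
    t = np.linspace(-1.0, 1.0, n)
    X = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ beta


def brute_dc(
    ts4d: np.ndarray, mask: np.ndarray, threshold: float, mode: str
) -> np.ndarray:
    """Degree centrality from the full explicit correlation matrix."""
    coords = [tuple(c) for c in np.argwhere(mask)]
    n = len(coords)
    series = np.array([_detrend1(ts4d[c]) for c in coords])
    out = np.zeros(ts4d.shape[:3])
    for i in range(n):
        total = 0.0
        for j in range(n):
            if i == j:
                continue
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > threshold:
                total += 1.0 if mode == "binary" else np.arctanh(
                    np.clip(r, -(1 - 1e-7), 1 - 1e-7)
                )
        out[coords[i]] = total
    return out


def brute_falff(ts4d: np.ndarray, mask: np.ndarray, tr: float, band) -> np.ndarray:
    """fALFF from an explicit per-voxel periodogram."""
    out = np.zeros(ts4d.shape[:3])
    lo, hi = band
    for idx in np.argwhere(mask):
        x = _detrend1(ts4d[tuple(idx)])
        amp = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=tr)
        pos = freqs > 0
        sel = pos & (freqs >= lo) & (freqs <= hi)
        total = amp[pos].sum()
        out[tuple(idx)] = amp[sel].sum() / total if total > 0 else 0.0
    return out


def brute_seed_ifc(ts4d: np.ndarray, mask: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Seed correlations (Fisher-z) via per-voxel np.corrcoef calls."""
    seed_ts = _detrend1(ts4d[seed_mask].mean(axis=0))
    out = np.zeros(ts4d.shape[:3])
    for idx in np.argwhere(mask):
        r = np.corrcoef(_detrend1(ts4d[tuple(idx)]), seed_ts)[0, 1]
        out[tuple(idx)] = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))
    return out


def brute_overlap_curve(a_map, b_map, mask, z_values, a_sign, b_sign):
    """Overlap percentages by looping thresholds over boolean masks."""
    out = np.zeros(len(z_values))
    for i, z in enumerate(z_values):
        ma = ((a_map >= z) if a_sign > 0 else (a_map <= -z)) & mask
        mb = ((b_map >= z) if b_sign > 0 else (b_map <= -z)) & mask
        na, nb = ma.sum(), mb.sum()
        if na == 0 or nb == 0:
            out[i] = 0.0
        else:
            ni = (ma & mb).sum()
            out[i] = 100.0 * 0.5 * (ni / na + ni / nb)
    return out


def brute_flood_fill_clusters(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by BFS flood fill; returns voxel sets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(mask.shape, dtype=bool)
    clusters = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(np.array(v) + off)
                if all(0 <= wi < si for wi, si in zip(w, mask.shape)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        clusters.append(comp)
    return clusters
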