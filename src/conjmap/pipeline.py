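"""End-to-end orchestration: inputs -> Z-maps -> conjunction -> decision.

`analyze_pair` is the library entry point for a prepared Z-map pair;
`run_pipeline` drives a whole run from a YAML/dict config (simulated
pair, Z-map files, or subject-level cohorts), writes TSV/JSON/NIfTI/PNG
outputs and a manifest, and is deterministic for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conjunction import (
    ZMapPair,
    build_threshold_grid,
    scenario_overlap_curves,
)
from .group_zmaps import fit_voxelwise_glm
from .null_model import (
    average_smoothness,
    decide_significance,
    estimate_fwhm,
    monte_carlo_null,
)
from .rfmri_metrics import MetricConfig, compute_derivative
from .synthetic_data import (
    CohortSpec,
    FieldSpec,
    PlantedEffect,
    cohort_derivative_maps,
    make_synthetic_atlas,
    plant_zmap_pair,
    simulate_cohort,
)
from .volume_io import MaskedVolume, read_timeseries, read_volume, write_mask, write_volume

logger = logging.getLogger(__name__)

__all__ = ["analyze_pair", "run_pipeline", "load_config"]


def analyze_pair(
    pair: ZMapPair,
    grid=None,
    iterations: int = 500,
    seed: int | None = None,
    consistency: float = 0.70,
    display_z: float = 2.58,
    target_fwhm_mm: float | None = None,
) -> dict:
    """Full conjunction analysis of one Z-map pair.

    Estimates per-map smoothness, averages it, builds the matched Monte
    Carlo null, computes the four scenario overlap curves, and renders
    the consistency decision per scenario.
    """
    if grid is None:
        grid = build_threshold_grid()
    sm_a = estimate_fwhm(pair.map_a)
    sm_b = estimate_fwhm(pair.map_b)
    sm = average_smoothness(sm_a, sm_b)
    if target_fwhm_mm is None:
        target_fwhm_mm = sm.combined_fwhm_mm
        if np.isnan(target_fwhm_mm):
            target_fwhm_mm = 0.0
    template = MaskedVolume(
        np.zeros(pair.map_a.shape), pair.map_a.affine, pair.shared_mask
    )
    null = monte_carlo_null(template, target_fwhm_mm, grid, iterations, seed)
    curves = scenario_overlap_curves(pair, grid)
    results = {
        name: decide_significance(
            curve, null, consistency=consistency, pair=pair, display_z=display_z
        )
        for name, curve in curves.items()
    }
    return {
        "grid": grid,
        "smoothness": {"map_a": sm_a, "map_b": sm_b, "average": sm},
        "target_fwhm_mm": float(target_fwhm_mm),
        "null": null,
        "curves": curves,
        "results": results,
    }


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _build_pair_from_config(cfg: dict, seed: int, hashes: dict) -> ZMapPair:
    inp = cfg.get("input")
    if not inp or "kind" not in inp:
        raise ValueError("config requires input.kind (simulate_pair | zmaps | cohorts)")
    kind = inp["kind"]
    if kind == "simulate_pair":
        fs = inp.get("field", {})
        spec = FieldSpec(
            shape=tuple(fs.get("shape", (32, 32, 32))),
            voxel_size_mm=tuple(fs.get("voxel_size_mm", (3.0, 3.0, 3.0))),
            fwhm_mm=float(fs.get("fwhm_mm", 6.0)),
            mask_kind=fs.get("mask_kind", "ellipsoid"),
            seed=seed,
        )
        effects = [
            PlantedEffect(
                center_voxel=tuple(e["center_voxel"]),
                radius_voxels=float(e["radius_voxels"]),
                amplitude_z=float(e["amplitude_z"]),
                scenario=e["scenario"],
                jitter_voxels=int(e.get("jitter_voxels", 0)),
            )
            for e in inp.get("effects", [])
        ]
        return plant_zmap_pair(spec, effects)
    if kind == "zmaps":
        for key in ("map_a", "map_b"):
            if key not in inp:
                raise ValueError(f"input.kind=zmaps requires input.{key} (NIfTI path)")
            hashes[key] = _sha256(Path(inp[key]))
        va = read_volume(inp["map_a"])
        vb = read_volume(inp["map_b"])
        if "mask" in inp:
            hashes["mask"] = _sha256(Path(inp["mask"]))
            m = read_volume(inp["mask"]).data > 0
            va = MaskedVolume(va.data, va.affine, va.mask & m)
            vb = MaskedVolume(vb.data, vb.affine, vb.mask & m)
        return ZMapPair(
            va, vb,
            a_positive=inp.get("a_positive", "ASD>NT"),
            b_positive=inp.get("b_positive", "M>F"),
        )
    if kind == "cohorts":
        zmaps = {}
        for label in ("a", "b"):
            sub = inp.get(label)
            if sub is None:
                raise ValueError(f"input.kind=cohorts requires input.{label}")
            zmaps[label] = _cohort_zmap(sub, seed, label, hashes)
        return ZMapPair(
            zmaps["a"].volume, zmaps["b"].volume,
            a_positive=zmaps["a"].positive_direction,
            b_positive=zmaps["b"].positive_direction,
        )
    raise ValueError(f"unknown input.kind {kind!r}")


def _cohort_zmap(sub: dict, seed: int, label: str, hashes: dict):
    if "simulate" in sub:
        sim = dict(sub["simulate"])
        sim.setdefault("seed", seed + (0 if label == "a" else 1))
        for key in ("shape", "voxel_size_mm", "effect_center", "group_labels"):
            if key in sim:
                sim[key] = tuple(sim[key])
        ds = simulate_cohort(CohortSpec(**sim))
        maps = cohort_derivative_maps(ds)
        # the second group label is the case/positive direction
        return fit_voxelwise_glm(maps, ds.phenotype, positive_group=ds.spec.group_labels[1])
    if "phenotype" not in sub:
        raise ValueError(
            f"cohort {label!r}: starting from 4D data requires a 'phenotype' "
            "TSV path alongside 'timeseries'"
        )
    if "timeseries" not in sub:
        raise ValueError(f"cohort {label!r}: requires 'timeseries' (list of 4D NIfTI)")
    pheno = pd.read_csv(sub["phenotype"], sep="\t")
    hashes[f"{label}_phenotype"] = _sha256(Path(sub["phenotype"]))
    metric_cfg = MetricConfig(**sub.get("metric", {}))
    maps = []
    for sid, path in zip(pheno["subject_id"], sub["timeseries"]):
        ts, template, tr = read_timeseries(path)
        if tr > 0 and "tr_seconds" not in sub.get("metric", {}):
            metric_cfg.tr_seconds = tr
        hashes[f"{label}_{sid}"] = _sha256(Path(path))
        maps.append(compute_derivative(ts, template, metric_cfg, subject_id=sid))
    return fit_voxelwise_glm(maps, pheno, positive_group=sub.get("positive_group"))


def _curves_table(curves, null) -> pd.DataFrame:
    rows = []
    for name, curve in curves.items():
        for i in range(len(curve.grid)):
            rows.append(
                {
                    "scenario": name,
                    "p": curve.grid.p_values[i],
                    "z_cut": curve.grid.z_values[i],
                    "count_a": int(curve.count_a[i]),
                    "count_b": int(curve.count_b[i]),
                    "count_intersection": int(curve.count_intersection[i]),
                    "overlap_percent": curve.overlap_percent[i],
                    "null_p005": null.band(0.5)[i],
                    "null_median": null.band(50.0)[i],
                    "null_p995": null.band(99.5)[i],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full pipeline from a config; write the result bundle.

    Outputs under ``out_dir``: overlap_curves.tsv (curves + null bands),
    decisions.json, conjunction_<scenario>.nii.gz display masks,
    network_attribution.tsv (when an atlas is configured), Fig-style
    PNGs, and manifest.json. Identical config + seed reproduce
    byte-identical TSV/JSON outputs.
    """
    cfg = load_config(config)
    if out_dir is None:
        out_dir = cfg.get("out_dir")
    if out_dir is None:
        raise ValueError("an output directory is required (out_dir)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    hashes: dict[str, str] = {}
    try:
        pair = _build_pair_from_config(cfg, seed, hashes)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    conj_cfg = cfg.get("conjunction", {})
    grid = build_threshold_grid(
        p_start=float(conj_cfg.get("p_start", 0.05)),
        p_end=float(conj_cfg.get("p_end", 0.0001)),
        step=float(conj_cfg.get("step", 0.0001)),
        tail=conj_cfg.get("tail", "one_tailed"),
    )
    null_cfg = cfg.get("null", {})
    dec_cfg = cfg.get("decision", {})
    try:
        analysis = analyze_pair(
            pair,
            grid=grid,
            iterations=int(null_cfg.get("iterations", 500)),
            seed=seed,
            consistency=float(dec_cfg.get("consistency", 0.70)),
            display_z=float(dec_cfg.get("display_z", 2.58)),
            target_fwhm_mm=null_cfg.get("target_fwhm_mm"),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'conjunction/null' failed: {exc}") from exc

    curves, null, results = analysis["curves"], analysis["null"], analysis["results"]

    table = _curves_table(curves, null)
    table.to_csv(out_dir / "overlap_curves.tsv", sep="\t", index=False, float_format="%.6f")

    decisions = {
        name: {
            "significant": bool(res.significant),
            "exceedance_count": res.exceedance_count,
            "required_count": res.required_count,
            "n_thresholds": res.n_thresholds,
            "display_z": res.display_z,
            "display_mask_voxels": int(res.display_mask.sum()),
        }
        for name, res in results.items()
    }
    meta = {
        "seed": seed,
        "iterations": null.iterations,
        "target_fwhm_mm": analysis["target_fwhm_mm"],
        "smoothness_map_a_mm": [
            None if np.isnan(f) else f for f in analysis["smoothness"]["map_a"].fwhm_mm
        ],
        "smoothness_map_b_mm": [
            None if np.isnan(f) else f for f in analysis["smoothness"]["map_b"].fwhm_mm
        ],
        "consistency": float(dec_cfg.get("consistency", 0.70)),
        "quantile_definition": "linear-interpolation empirical percentile",
        "tail": grid.tail,
    }
    (out_dir / "decisions.json").write_text(
        json.dumps({"scenarios": decisions, "parameters": meta},
                   indent=2, sort_keys=True, allow_nan=False, default=_json_default)
    )

    for name, res in results.items():
        write_mask(res.display_mask, pair.map_a.affine, out_dir / f"conjunction_{name}.nii.gz")
    write_volume(pair.map_a, out_dir / "zmap_a.nii.gz")
    write_volume(pair.map_b, out_dir / "zmap_b.nii.gz")

    attribution_tables = _run_attribution(cfg, pair, results, seed, out_dir)

    if cfg.get("plots", True):
        from .plotting import plot_network_bars, plot_overlap_curves

        plot_overlap_curves(curves, null, out_dir / "overlap_curves.png")
        for name, tab in attribution_tables.items():
            plot_network_bars(tab, out_dir / f"network_{name}.png", title=name)

    manifest = {
        "conjmap_version": __version__,
        "numpy_version": np.__version__,
        "config": _jsonable_cfg(cfg),
        "seed": seed,
        "input_hashes": hashes,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default)
    )
    return {
        "pair": pair,
        "analysis": analysis,
        "decisions": decisions,
        "attribution": attribution_tables,
        "out_dir": out_dir,
    }


def _run_attribution(cfg, pair, results, seed, out_dir) -> dict:
    from .attribution import AtlasVolume, network_attribution

    att_cfg = cfg.get("attribution")
    if not att_cfg:
        return {}
    if "atlas" in att_cfg and att_cfg["atlas"]:
        vol = read_volume(att_cfg["atlas"])
        atlas = AtlasVolume(vol, {int(k): v for k, v in att_cfg.get("names", {}).items()})
    else:
        atlas_vol = make_synthetic_atlas(
            MaskedVolume(np.zeros(pair.map_a.shape), pair.map_a.affine, pair.shared_mask),
            n_labels=int(att_cfg.get("synthetic_labels", 7)),
            seed=seed,
        )
        atlas = AtlasVolume(atlas_vol)
    tables = {}
    for name, res in results.items():
        if res.significant and res.display_mask.any():
            tab = network_attribution(res.display_mask, atlas)
            tab.to_csv(
                out_dir / f"network_attribution_{name}.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
            tables[name] = tab
    return tables


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _jsonable_cfg(cfg):
    return json.loads(json.dumps(cfg, default=_json_default))
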