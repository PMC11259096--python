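"""Config-driven orchestration: phantoms → masks → metrics → statistics.

A single YAML config describes either a phantom experiment (conditions
mapped to vessel-phantom recipes, each imaged as several ROIs per gel) or
a manifest of existing mask files, plus per-stage parameters. All
randomness flows from one root seed through named substreams, so a rerun
with the same config and seed is byte-identical, and every applied default
is recorded in the provenance log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantoms import VesselPhantomSpec, generate_vessel_phantom
from .preprocess import preprocess_stack
from .skeleton import average_rois, build_graph, measure, skeletonize
from .stacks import ImageStack, read_stack, stack_volume_mm3
from .stats import GroupData, route_and_test

__all__ = ["validate_config", "run", "load_config", "DEMO_CONFIG"]

_ALLOWED_TOP = {
    "seed", "output_dir", "conditions", "inputs", "preprocess", "skeleton",
    "stats", "metric",
}
_PREPROCESS_DEFAULTS = {
    "sigma_um": 2.0,
    "filter_method": "median",
    "filter_size_um": 3.0,
    "threshold_method": "otsu_per_slice",
    "threshold_value": None,
    "min_object_voxels": 27,
    "fill_holes": False,
}
_SKELETON_DEFAULTS = {"prune_um": 3.0}
_STATS_DEFAULTS = {"alpha": 0.05, "trim": 0.2, "dunn_adjust": "holm"}

# two phantom conditions differing in target segment count: enough signal
# for the routed statistics to flag a group difference on small grids
DEMO_CONFIG = {
    "seed": 7,
    "metric": "total_length_um",
    "conditions": {
        "sparse": {
            "topology": "random_tree",
            "n_segments": 4,
            "n_gels": 3,
            "rois_per_gel": 3,
            "grid_shape": [16, 100, 100],
            "voxel_size": [2.0, 2.0, 2.0],
            "tube_radius_um": 4.0,
            "segment_length_um": 40.0,
        },
        "dense": {
            "topology": "random_tree",
            "n_segments": 9,
            "n_gels": 3,
            "rois_per_gel": 3,
            "grid_shape": [16, 100, 100],
            "voxel_size": [2.0, 2.0, 2.0],
            "tube_radius_um": 4.0,
            "segment_length_um": 35.0,
        },
    },
    # sparse stacks: threshold on the full-volume histogram, prune at 2x radius
    "preprocess": {"threshold_method": "otsu_global"},
    "skeleton": {"prune_um": 8.0},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def validate_config(config: dict | str | Path) -> list[str]:
    """Schema / sanity check without running anything; returns error list."""
    if not isinstance(config, dict):
        try:
            config = load_config(config)
        except Exception as exc:  # malformed YAML is itself a finding
            return [f"unreadable config: {exc}"]
    errors: list[str] = []
    unknown = set(config) - _ALLOWED_TOP
    if unknown:
        errors.append(
            f"unknown keys {sorted(unknown)}; allowed: {sorted(_ALLOWED_TOP)}"
        )
    if "conditions" not in config and "inputs" not in config:
        errors.append("config needs 'conditions' (phantom specs) or 'inputs'")
    pp = {**_PREPROCESS_DEFAULTS, **config.get("preprocess", {})}
    if pp["sigma_um"] < 0:
        errors.append("preprocess.sigma_um must be non-negative")
    if pp["filter_size_um"] <= 0:
        errors.append("preprocess.filter_size_um must be positive")
    if pp["min_object_voxels"] < 0:
        errors.append("preprocess.min_object_voxels must be non-negative")
    sk = {**_SKELETON_DEFAULTS, **config.get("skeleton", {})}
    if sk["prune_um"] < 0:
        errors.append("skeleton.prune_um must be non-negative")
    for cond, spec in (config.get("conditions") or {}).items():
        if not isinstance(spec, dict):
            errors.append(f"condition {cond!r} must be a mapping")
            continue
        if spec.get("tube_radius_um", 3.0) <= 0:
            errors.append(f"condition {cond!r}: tube_radius_um must be positive")
    for item in config.get("inputs") or []:
        p = item.get("path") if isinstance(item, dict) else None
        if p is None:
            errors.append(f"input entry {item!r} lacks a 'path'")
        elif not Path(p).exists():
            errors.append(f"input file not found: {p}")
    return errors


def _phantom_spec(cond_cfg: dict, seed: int) -> VesselPhantomSpec:
    fields = {f.name for f in dataclasses.fields(VesselPhantomSpec)}
    kw = {k: v for k, v in cond_cfg.items() if k in fields}
    for key in ("grid_shape", "voxel_size"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return VesselPhantomSpec(rng_seed=seed, **kw)


def run(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the report bundle (also on disk).

    Per-gel metrics (ROIs averaged) land in ``metrics.csv``, the routed
    group comparison in ``stats.json``, and every parameter — explicit or
    defaulted — in ``provenance.json``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(output_dir or config.get("output_dir", "angiokit_out"))
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    pp = {**_PREPROCESS_DEFAULTS, **config.get("preprocess", {})}
    sk = {**_SKELETON_DEFAULTS, **config.get("skeleton", {})}
    st = {**_STATS_DEFAULTS, **config.get("stats", {})}
    metric = config.get("metric", "total_length_per_mm3")

    rows: list[dict] = []
    if "conditions" in config:
        root = np.random.SeedSequence(seed)
        cond_names = sorted(config["conditions"])
        streams = {c: s for c, s in zip(cond_names, root.spawn(len(cond_names)))}
        for cond in cond_names:
            ccfg = config["conditions"][cond]
            n_gels = int(ccfg.get("n_gels", 3))
            rois = int(ccfg.get("rois_per_gel", 3))
            child_seeds = streams[cond].generate_state(n_gels * rois) & 0x7FFFFFFF
            idx = 0
            for gel in range(n_gels):
                roi_metrics = []
                for _ in range(rois):
                    spec = _phantom_spec(ccfg, int(child_seeds[idx]))
                    idx += 1
                    stack, _gt = generate_vessel_phantom(spec)
                    roi_metrics.append(_measure_stack(stack, pp, sk))
                gel_metrics = average_rois(roi_metrics)
                row = {"condition": cond, "gel": f"{cond}-{gel}"}
                row.update(gel_metrics.to_dict())
                row.pop("units", None)
                rows.append(row)
    else:
        for item in config["inputs"]:
            stack = read_stack(
                item["path"], calibration_override=item.get("voxel_size")
            )
            m = _measure_stack(stack, pp, sk)
            row = {
                "condition": item.get("condition", "all"),
                "gel": item.get("sample", Path(item["path"]).stem),
            }
            row.update(m.to_dict())
            row.pop("units", None)
            rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(out / "metrics.csv", index=False)

    report: dict = {"metrics_csv": str(out / "metrics.csv"), "n_samples": len(rows)}
    by_cond = table.groupby("condition")[metric]
    if table["condition"].nunique() >= 2 and by_cond.size().min() >= 3:
        data = GroupData(
            {c: g.to_numpy() for c, g in by_cond}, metric=metric
        )
        result = route_and_test(
            data,
            alpha=st["alpha"],
            trim=st["trim"],
            dunn_adjust=st["dunn_adjust"],
        )
        with open(out / "stats.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        report["stats"] = result.to_dict()

    provenance = {
        "angiokit_version": __version__,
        "seed": seed,
        "metric": metric,
        "preprocess": pp,
        "skeleton": sk,
        "stats": st,
        "config": {k: v for k, v in config.items() if k != "inputs"},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    report["provenance"] = provenance
    report["metrics"] = rows
    return report


def _measure_stack(stack: ImageStack, pp: dict, sk: dict):
    mask = preprocess_stack(stack, **pp)
    skel = skeletonize(mask)
    graph = build_graph(skel, prune_um=sk["prune_um"])
    return measure(graph, stack_volume_mm3(stack))
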