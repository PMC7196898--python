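"""End-to-end orchestration: validated run configs and reproducible reports.

A run config is a plain nested dict (JSON/YAML-compatible).  Supported
stages: ``simulate`` (write synthetic fixtures), ``callose`` (detect and
summarize puncta in a mock/chitin pair of rendered stacks) and
``compare`` (treatment statistics on the summaries).  Reports embed the
seed and a config hash so any run is reconstructable from its report.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import InvalidArgumentError
from .image_quant import SpotDetectionParams, detect_spots, summarize_spot_fluorescence
from .synthetic_data import (
    CountSimSpec,
    DecaySimSpec,
    FrapSimSpec,
    make_cell_mosaic,
    render_membrane_stack,
    simulate_bombardment,
    simulate_decay,
    simulate_frap,
    simulate_luminescence,
)
from . import io as pio

__all__ = ["DEFAULT_CONFIG", "validate_config", "config_hash", "run_pipeline"]

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "pdquant_run",
    "stages": ["simulate", "callose", "compare"],
    "mosaic": {"width": 192, "height": 192, "n_cells": 8},
    "render": {
        "n_z": 5,
        "pd_per_100um": 8.0,
        "pd_index_true": 6.0,
        "pm_intensity": 8.0,
        "psf_sigma": 1.0,
        "read_noise_sd": 2.0,
        "chitin_amplitude_ratio": 1.5,
        "n_images_per_condition": 3,
    },
    "detection": {
        "smooth_sigma": 1.0,
        "background_radius": 5,
        "threshold_mode": "otsu",
        "threshold_value": 0.0,
        "min_voxels": 3,
        "max_voxels": 200,
        "connectivity": 26,
    },
    "anisotropy_variant": "standard",
    "tau_av_weighting": "amplitude",
    "mobile_fraction_method": "endpoint",
    "alpha": 0.05,
}

_RANGES = {
    ("mosaic", "width"): (32, 4096),
    ("mosaic", "height"): (32, 4096),
    ("mosaic", "n_cells"): (1, 10_000),
    ("render", "n_z"): (1, 256),
    ("render", "pd_per_100um"): (0.0, 1e4),
    ("render", "pd_index_true"): (1.0, 1e3),
    ("render", "pm_intensity"): (1e-6, 1e9),
    ("render", "psf_sigma"): (0.0, 50.0),
    ("render", "read_noise_sd"): (0.0, 1e6),
    ("render", "chitin_amplitude_ratio"): (0.0, 1e3),
    ("render", "n_images_per_condition"): (1, 1000),
    ("detection", "smooth_sigma"): (0.0, 50.0),
    ("detection", "background_radius"): (0, 500),
    ("detection", "min_voxels"): (1, 10**9),
    ("detection", "max_voxels"): (2, 10**9),
    ("alpha",): (0.0, 1.0),
}

_CHOICES = {
    ("detection", "threshold_mode"): ("otsu", "absolute", "percentile"),
    ("anisotropy_variant",): ("standard", "literal", "classic"),
    ("tau_av_weighting",): ("amplitude", "intensity"),
    ("mobile_fraction_method",): ("endpoint", "exp_fit"),
}

_KNOWN_STAGES = ("simulate", "callose", "compare")


def _walk_unknown(cfg, defaults, path=()):
    errors = []
    for key, value in cfg.items():
        if key not in defaults:
            errors.append(f"unknown key {'.'.join(path + (key,))!r}")
        elif isinstance(value, dict) and isinstance(defaults[key], dict):
            errors.extend(_walk_unknown(value, defaults[key], path + (key,)))
    return errors


def validate_config(config: dict | None) -> dict:
    """Merge with defaults and validate; raise with every violation listed."""
    config = config or {}
    errors = _walk_unknown(config, DEFAULT_CONFIG)
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        elif key in merged:
            merged[key] = value

    for path, (lo, hi) in _RANGES.items():
        node = merged
        for p in path[:-1]:
            node = node[p]
        val = node[path[-1]]
        if not (lo <= val <= hi):
            errors.append(f"{'.'.join(path)}={val} outside [{lo}, {hi}]")
    for path, choices in _CHOICES.items():
        node = merged
        for p in path[:-1]:
            node = node[p]
        if node[path[-1]] not in choices:
            errors.append(f"{'.'.join(path)} must be one of {choices}")
    det = merged["detection"]
    if det["min_voxels"] >= det["max_voxels"]:
        errors.append("detection.min_voxels must be < detection.max_voxels")
    if not 0 < merged["alpha"] < 1:
        errors.append(f"alpha={merged['alpha']} outside (0, 1)")
    for stage in merged["stages"]:
        if stage not in _KNOWN_STAGES:
            errors.append(f"unknown stage {stage!r}")
    if errors:
        raise InvalidArgumentError("invalid config: " + "; ".join(errors))
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _render_condition(cfg, condition, seed, out_dir):
    """Render n images for one condition; chitin scales punctum amplitude."""
    r = cfg["render"]
    m = cfg["mosaic"]
    ratio = r["chitin_amplitude_ratio"] if condition == "chitin" else 1.0
    # the amplitude ratio acts through the constructed PD enrichment
    pdi = 1.0 + (r["pd_index_true"] - 1.0) * ratio
    records = []
    for i in range(r["n_images_per_condition"]):
        sub = seed + 1000 * i
        mosaic = make_cell_mosaic(m["width"], m["height"], m["n_cells"], sub)
        stack, truth = render_membrane_stack(
            mosaic,
            n_z=r["n_z"],
            pd_per_100um=r["pd_per_100um"],
            pd_index_true=pdi,
            pm_intensity=r["pm_intensity"],
            psf_sigma=r["psf_sigma"],
            read_noise_sd=r["read_noise_sd"],
            seed=sub + 1,
        )
        path = out_dir / f"{condition}_{i:02d}.tif"
        pio.write_stack(stack, path)
        records.append({"path": str(path), "n_truth_spots": len(truth.spot_truth)})
    return records


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured stages and return the run report (a dict).

    The report is also written to ``<out_dir>/report.json``.  Per-item
    failures (e.g. an unreadable image) are logged in the report and do
    not abort the run; ``report['status']`` is 'ok' only if no hard
    errors occurred.
    """
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "stages": {},
        "warnings": [],
        "status": "ok",
    }

    if "simulate" in cfg["stages"]:
        files = {}
        for cond, s in (("mock", seed), ("chitin", seed + 500_000)):
            files[cond] = _render_condition(cfg, cond, s, out_dir)
        # one example of each non-image modality, for downstream demos
        decay = simulate_decay(DecaySimSpec(), seed)
        pio.write_decay_csv(decay, out_dir / "decay_example.csv")
        frap = simulate_frap(FrapSimSpec(noise_sd=10.0), seed)
        pio.write_frap_csv(frap, out_dir / "frap_example.csv")
        lum = simulate_luminescence(noise_sd=5.0, seed=seed, well_id="A1")
        pio.write_lum_csv(lum, out_dir / "lum_example.csv")
        table = simulate_bombardment(CountSimSpec(), seed)
        table.to_csv(out_dir / "bombardment_example.csv", index=False)
        report["stages"]["simulate"] = {
            "images": files,
            "other_files": ["decay_example.csv", "frap_example.csv",
                            "lum_example.csv", "bombardment_example.csv"],
        }

    summaries = {}
    if "callose" in cfg["stages"]:
        params = SpotDetectionParams(**cfg["detection"])
        det_records = {"mock": [], "chitin": []}
        for cond in ("mock", "chitin"):
            for rec in report["stages"].get("simulate", {}).get("images", {}).get(cond, []):
                try:
                    stack = pio.read_stack(rec["path"])
                    spots = detect_spots(stack, params)
                    n, total, mean = summarize_spot_fluorescence(spots)
                    det_records[cond].append(
                        {"path": rec["path"], "n_spots": n,
                         "total_fluorescence": total, "mean_spot_fluorescence": mean}
                    )
                except Exception as exc:  # per-item failure: log, continue
                    report["warnings"].append(f"{rec['path']}: {exc}")
        report["stages"]["callose"] = det_records
        summaries = det_records

    if "compare" in cfg["stages"] and summaries:
        means = {
            cond: [r["mean_spot_fluorescence"] for r in recs if r["n_spots"] > 0]
            for cond, recs in summaries.items()
        }
        comp = {}
        if all(len(v) > 0 for v in means.values()):
            mock_mean = float(np.mean(means["mock"]))
            chitin_mean = float(np.mean(means["chitin"]))
            comp = {
                "mock_mean_spot_fluorescence": mock_mean,
                "chitin_mean_spot_fluorescence": chitin_mean,
                "direction": "chitin>mock" if chitin_mean > mock_mean else "chitin<=mock",
            }
        else:
            report["warnings"].append("compare: a condition had no detected spots")
        report["stages"]["compare"] = comp

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
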