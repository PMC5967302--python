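"""Config-driven orchestration of generators and analyses.

A run is described by a YAML/JSON config with a ``task`` (simulate,
morphometry, cortical, trap_calibration, tether, traces), input paths,
task parameters and a seed.  ``run`` executes the task, writes its tables
and summaries into an output directory, and finishes with a manifest
(inputs, parameters, seed, package version, SHA-256 checksums of every
output).  Identical (config, seed) pairs reproduce byte-identical numeric
outputs; nothing time-dependent enters the manifest.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cortical_profile import CorticalConfig, cortex_cytoplasm_ratio
from .errors import ConfigError
from .morphometry import MorphometryConfig, analyze_field, records_to_frame
from .signal_traces import CtQuad, Trace, basal_level, delta_ratio, fold_change_ddct
from .synthetic_data import (
    CorticalSpec,
    FieldSpec,
    PopulationSpec,
    TetherSimParams,
    TraceSpec,
    TrapSimParams,
    generate_cortical_image,
    generate_fura2_trace,
    generate_intensity_population,
    generate_syncytium_field,
    sample_field_spec,
    simulate_tether_pull,
    simulate_trapped_bead,
)
from .trap_mechanics import (
    ROOM_TEMPERATURE_K,
    BeadTrack,
    StageTrack,
    TrapCalibration,
    force_extension_curve,
    linear_region_fit,
    stiffness_equipartition,
)

logger = logging.getLogger("myoquant")

TASKS = ("simulate", "morphometry", "cortical", "trap_calibration", "tether", "traces")

SIMULATE_KINDS = ("syncytium", "cortical", "bead", "tether", "fura2", "population")

# Per-task schema: required input keys and parameter defaults.  Unknown
# keys anywhere are rejected with their path.
_SCHEMA: dict[str, dict[str, Any]] = {
    "simulate": {
        "inputs": (),
        "params": {"kind": "bead", "overrides": {}},
    },
    "morphometry": {
        "inputs": ("labels", "nuclei"),
        "optional_inputs": ("myhc",),
        "params": {
            "fusion_nuclei_threshold": 16,
            "elongation_ar_threshold": 3.0,
            "pixel_size": 1.0,
            "elongation_multinucleate_only": False,
            "myhc_threshold": None,
        },
    },
    "cortical": {
        "inputs": ("image", "mask"),
        "params": {
            "pixel_size": 1.0,
            "peak_band": [0.0, 5.0],
            "mean_band": [2.0, 7.0],
            "rectangle_width": 1.0,
            "rectangle_spacing": 2.0,
            "profile_depth": 12.0,
            "profile_step": 0.2,
        },
    },
    "trap_calibration": {
        "inputs": ("track",),
        "params": {"temperature": ROOM_TEMPERATURE_K, "method": "gaussian_fit"},
    },
    "tether": {
        "inputs": ("bead", "stage"),
        "params": {
            "stiffness": None,  # pN/μm; required unless a calibration file is given
            "calibration": None,  # path to a trap_calibration JSON
            "temperature": ROOM_TEMPERATURE_K,
            "baseline_window": 0.5,
            "axis": "stage",
            "r2_min": 0.98,
            "min_points": 10,
        },
    },
    "traces": {
        "inputs": ("trace",),
        "optional_inputs": ("control",),
        "params": {
            "statistic": "delta_ratio",  # delta_ratio | basal_level | fold_change
            "t_ref": 60.0,
            "basal_window": [0.0, 60.0],
            "ct": None,  # 4-list for fold_change
        },
    },
}


@dataclasses.dataclass
class RunConfig:
    """Validated, normalized run description."""

    task: str
    inputs: dict[str, str]
    params: dict[str, Any]
    seed: int = 0


def validate_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a YAML/JSON config file (or dict).

    Fills documented defaults, rejects unknown tasks and unknown keys
    (reported with their key path), and checks basic invariants before
    any computation happens.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = copy.deepcopy(source)  # never mutate the caller's dict
    if not isinstance(raw, dict) or not raw:
        raise ConfigError("config is empty or not a mapping")
    unknown_top = set(raw) - {"task", "inputs", "params", "seed"}
    if unknown_top:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown_top)}")
    task = raw.get("task")
    if task not in TASKS:
        raise ConfigError(f"unknown task: {task!r}; expected one of {TASKS}")
    schema = _SCHEMA[task]

    inputs = dict(raw.get("inputs") or {})
    required = set(schema["inputs"])
    allowed = required | set(schema.get("optional_inputs", ()))
    unknown = set(inputs) - allowed
    if unknown:
        raise ConfigError(f"unknown input key(s) under 'inputs': {sorted(unknown)}")
    missing = required - set(inputs)
    if missing:
        raise ConfigError(f"missing required input(s): {sorted(missing)}")
    for key, path in inputs.items():
        if not Path(path).exists():
            raise ConfigError(f"input '{key}' does not exist: {path}")

    params = dict(schema["params"])
    user_params = dict(raw.get("params") or {})
    unknown = set(user_params) - set(params)
    if unknown:
        raise ConfigError(f"unknown parameter key(s) under 'params': {sorted(unknown)}")
    params.update(user_params)

    if "pixel_size" in params and params["pixel_size"] <= 0:
        raise ConfigError("params.pixel_size must be positive")
    if task == "simulate" and params["kind"] not in SIMULATE_KINDS:
        raise ConfigError(
            f"unknown simulate kind: {params['kind']!r}; expected one of "
            f"{SIMULATE_KINDS}"
        )

    seed = int(raw.get("seed", 0))
    return RunConfig(task=task, inputs=inputs, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spec_with_overrides(cls, overrides: dict, seed: int):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - field_names
    if unknown:
        raise ConfigError(f"unknown override(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(overrides)
    for key in ("semi_axes", "center", "image_shape"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "seed" in field_names:
        kwargs.setdefault("seed", seed)
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Task implementations
# ---------------------------------------------------------------------------

def _run_simulate(config: RunConfig, out: Path) -> list[Path]:
    kind = config.params["kind"]
    overrides = dict(config.params.get("overrides") or {})
    files: list[Path] = []
    if kind == "syncytium":
        if "spec_seed" in overrides:
            spec_seed = overrides.pop("spec_seed")
            field_kwargs = {
                k: overrides.pop(k) for k in ("n_cells",) if k in overrides
            }
            spec = sample_field_spec(spec_seed, **field_kwargs)
        else:
            spec = _spec_with_overrides(FieldSpec, overrides, config.seed)
        result = generate_syncytium_field(spec)
        tifffile.imwrite(out / "labels.tif", result.label_mask)
        tifffile.imwrite(out / "myhc.tif", result.myhc)
        result.nuclei.to_csv(out / "nuclei.csv", index=False)
        result.cell_table.to_csv(out / "cells_truth.csv", index=False)
        _write_json(out / "ground_truth.json", result.truth.as_dict())
        files = [out / n for n in
                 ("labels.tif", "myhc.tif", "nuclei.csv", "cells_truth.csv",
                  "ground_truth.json")]
    elif kind == "cortical":
        spec = _spec_with_overrides(CorticalSpec, overrides, config.seed)
        mask, image = generate_cortical_image(spec)
        tifffile.imwrite(out / "mask.tif", mask.astype(np.uint16))
        tifffile.imwrite(out / "image.tif", image)
        _write_json(
            out / "ground_truth.json",
            {
                "cortex_level": spec.cortex_level,
                "interior_level": spec.interior_level,
                "contrast": spec.cortex_level / max(spec.interior_level, 1e-12),
            },
        )
        files = [out / n for n in ("mask.tif", "image.tif", "ground_truth.json")]
    elif kind == "bead":
        params = _spec_with_overrides(TrapSimParams, overrides, config.seed)
        track = simulate_trapped_bead(params)
        track.to_csv(out / "bead_track.csv")
        _write_json(out / "ground_truth.json", dict(track.meta))
        files = [out / "bead_track.csv", out / "ground_truth.json"]
    elif kind == "tether":
        params = _spec_with_overrides(TetherSimParams, overrides, config.seed)
        bead, stage = simulate_tether_pull(params)
        bead.to_csv(out / "bead_track.csv")
        stage.to_csv(out / "stage_track.csv")
        _write_json(out / "ground_truth.json", dict(bead.meta))
        files = [out / "bead_track.csv", out / "stage_track.csv",
                 out / "ground_truth.json"]
    elif kind == "fura2":
        spec = _spec_with_overrides(TraceSpec, overrides, config.seed)
        trace = generate_fura2_trace(spec)
        trace.to_csv(out / "trace.csv")
        _write_json(out / "ground_truth.json", dict(trace.meta))
        files = [out / "trace.csv", out / "ground_truth.json"]
    elif kind == "population":
        spec = _spec_with_overrides(PopulationSpec, overrides, config.seed)
        pop = generate_intensity_population(spec)
        pd.DataFrame(
            {"intensity": pop.intensities, "is_positive_true": pop.is_positive}
        ).to_csv(out / "population.csv", index=False)
        _write_json(
            out / "ground_truth.json",
            {"positive_fraction_true": spec.positive_fraction},
        )
        files = [out / "population.csv", out / "ground_truth.json"]
    return files


def _run_morphometry(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    mconfig = MorphometryConfig(
        fusion_nuclei_threshold=int(p["fusion_nuclei_threshold"]),
        elongation_ar_threshold=float(p["elongation_ar_threshold"]),
        pixel_size=float(p["pixel_size"]),
        elongation_multinucleate_only=bool(p["elongation_multinucleate_only"]),
    )
    labels = tifffile.imread(config.inputs["labels"])
    nuclei = pd.read_csv(config.inputs["nuclei"])
    myhc = (
        tifffile.imread(config.inputs["myhc"]) if "myhc" in config.inputs else None
    )
    records, summary = analyze_field(
        labels, nuclei, mconfig, myhc_image=myhc, myhc_threshold=p["myhc_threshold"]
    )
    records_to_frame(records).to_csv(out / "records.csv", index=False)
    _write_json(out / "summary.json", summary.as_dict())
    return [out / "records.csv", out / "summary.json"]


def _run_cortical(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    cconfig = CorticalConfig(
        peak_band=tuple(p["peak_band"]),
        mean_band=tuple(p["mean_band"]),
        rectangle_width=float(p["rectangle_width"]),
        rectangle_spacing=float(p["rectangle_spacing"]),
        profile_depth=float(p["profile_depth"]),
        profile_step=float(p["profile_step"]),
    )
    image = tifffile.imread(config.inputs["image"])
    mask = tifffile.imread(config.inputs["mask"]).astype(bool)
    ratio, n_used, table = cortex_cytoplasm_ratio(
        image, mask, float(p["pixel_size"]), cconfig
    )
    table.to_csv(out / "rectangles.csv", index=False)
    _write_json(
        out / "summary.json",
        {"cortex_cytoplasm_ratio": ratio, "n_rectangles_used": n_used},
    )
    return [out / "rectangles.csv", out / "summary.json"]


def _run_trap_calibration(config: RunConfig, out: Path) -> list[Path]:
    track = BeadTrack.from_csv(config.inputs["track"])
    calib = stiffness_equipartition(
        track,
        temperature=float(config.params["temperature"]),
        method=config.params["method"],
    )
    _write_json(out / "calibration.json", calib.as_dict())
    return [out / "calibration.json"]


def _run_tether(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    if p["calibration"] is not None:
        payload = json.loads(Path(p["calibration"]).read_text())
        calib = TrapCalibration(
            k_x=payload["k_x_pn_per_um"],
            temperature=payload["temperature_k"],
            n_frames=payload["n_frames"],
            method=payload["method"],
            variance_x=payload["variance_x_um2"],
        )
    elif p["stiffness"] is not None:
        calib = TrapCalibration(
            k_x=float(p["stiffness"]),
            temperature=float(p["temperature"]),
            n_frames=0,
            method="external",
            variance_x=float("nan"),
        )
    else:
        raise ConfigError("tether task needs params.stiffness or params.calibration")
    bead = BeadTrack.from_csv(config.inputs["bead"])
    stage = StageTrack.from_csv(config.inputs["stage"])
    curve = force_extension_curve(
        bead, stage, calib, baseline_window=float(p["baseline_window"]),
        axis=p["axis"],
    )
    fit = linear_region_fit(
        curve, r2_min=float(p["r2_min"]), min_points=int(p["min_points"])
    )
    curve.to_frame().to_csv(out / "force_extension.csv", index=False)
    _write_json(out / "linear_fit.json", fit.as_dict())
    return [out / "force_extension.csv", out / "linear_fit.json"]


def _run_traces(config: RunConfig, out: Path) -> list[Path]:
    p = config.params
    statistic = p["statistic"]
    if statistic == "fold_change":
        if not p["ct"] or len(p["ct"]) != 4:
            raise ConfigError(
                "fold_change needs params.ct = [target_sample, ref_sample, "
                "target_calibrator, ref_calibrator]"
            )
        value = fold_change_ddct(CtQuad(*[float(v) for v in p["ct"]]))
    else:
        trace = Trace.from_csv(config.inputs["trace"])
        if statistic == "delta_ratio":
            value = delta_ratio(trace, t_ref=float(p["t_ref"]))
        elif statistic == "basal_level":
            value = basal_level(trace, window=tuple(p["basal_window"]))
        else:
            raise ConfigError(f"unknown statistic: {statistic!r}")
    pd.DataFrame([{"statistic": statistic, "value": value}]).to_csv(
        out / "statistics.csv", index=False
    )
    _write_json(out / "statistics.json", {statistic: value})
    return [out / "statistics.csv", out / "statistics.json"]


_RUNNERS = {
    "simulate": _run_simulate,
    "morphometry": _run_morphometry,
    "cortical": _run_cortical,
    "trap_calibration": _run_trap_calibration,
    "tether": _run_tether,
    "traces": _run_traces,
}


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute a validated config and return the manifest.

    Writes all task outputs plus ``manifest.json`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("running task %s (seed %d) -> %s", config.task, config.seed, out)
    files = _RUNNERS[config.task](config, out)
    manifest = {
        "task": config.task,
        "seed": config.seed,
        "inputs": config.inputs,
        "parameters": config.params,
        "package_version": __version__,
        "outputs": {f.name: _sha256(f) for f in files},
    }
    _write_json(out / "manifest.json", manifest)
    logger.info("wrote %d output file(s)", len(files))
    return manifest
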