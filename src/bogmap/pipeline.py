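"""Configuration handling and staged pipeline orchestration.

Each stage reads its inputs from / writes its artefacts to an output
directory, together with a JSON run-manifest (stage name, config hash,
seeds, package version, input/output file checksums), so two runs with the
same config are byte-comparable.  The CLI in :mod:`bogmap.cli` is a thin
wrapper over these functions.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .classify import (
    extract_training_pixels,
    predict_map,
    train_forest,
    variable_importance,
)
from .compositing import build_feature_stack
from .emissions import compute_emissions, load_emission_factors, total_emissions
from .lucip import CLASS_NAMES, N_CLASSES, class_name
from .synthetic import (
    default_signatures,
    generate_class_map,
    generate_scene_series,
    generate_training_polygons,
)
from .validation import (
    accuracy_report,
    allocate_stratified_sample,
    area_based_overall_accuracy,
    build_confusion_matrix,
    draw_validation_points,
    simulate_reference_labels,
    unbiased_area_estimates,
)

import pandas as pd


def default_config() -> dict:
    with resources.files("bogmap.data").joinpath("default_config.yaml").open() as f:
        return yaml.safe_load(f)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a user config over the packaged defaults and validate it."""
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Range-check every parameter before any stage runs."""
    def err(msg: str) -> None:
        raise ValueError(f"config error: {msg}")

    if cfg["width"] <= 0 or cfg["height"] <= 0:
        err("width and height must be positive")
    p = np.asarray(cfg["proportions"], dtype=float)
    if p.shape != (N_CLASSES,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
        err(f"proportions must be {N_CLASSES} non-negative values summing to 1")
    if cfg["patch_scale"] < 1:
        err("patch_scale must be >= 1")
    if cfg["n_scenes"] < 1:
        err("n_scenes must be >= 1")
    lo, hi = cfg["cloud_fraction_range"]
    if not (0 <= lo <= hi <= 1):
        err("cloud_fraction_range must satisfy 0 <= lo <= hi <= 1")
    if not (0 <= cfg["max_cloud_fraction"] <= 1):
        err("max_cloud_fraction must lie in [0, 1]")
    if cfg["noise_sd"] < 0:
        err("noise_sd must be non-negative")
    if cfg["n_trees"] < 1:
        err("n_trees must be >= 1")
    if cfg["pixel_size_ha"] <= 0:
        err("pixel_size_ha must be positive")
    if cfg["total_n"] < N_CLASSES * cfg["min_per_stratum"]:
        err("total_n too small for the per-stratum floor")
    if len(cfg["n_per_class"]) != N_CLASSES:
        err(f"n_per_class must have length {N_CLASSES}")
    if not (0 <= cfg["label_error_rate"] < 1):
        err("label_error_rate must lie in [0, 1)")
    if cfg.get("ef_table") is not None and not Path(cfg["ef_table"]).exists():
        err(f"ef_table path not resolvable: {cfg['ef_table']}")
    for key in ("seed_truth", "seed_scenes", "seed_polygons", "seed_model",
                "seed_validation"):
        if not isinstance(cfg[key], int):
            err(f"{key} must be an explicit integer seed")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(outdir: Path, stage: str, cfg: dict, inputs: list[Path],
                   outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seeds": {k: cfg[k] for k in cfg if k.startswith("seed")},
        "inputs": {p.name: _checksum(p) for p in inputs if p.exists()},
        "outputs": {p.name: _checksum(p) for p in outputs if p.exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artefact {path} (run the '{producer}' stage first)"
        )
    return path


def stage_simulate(cfg: dict, outdir: str | Path) -> None:
    """Generate truth map, scene series and training polygons."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_class_map(
        cfg["width"], cfg["height"], cfg["proportions"],
        patch_scale=cfg["patch_scale"], seed=cfg["seed_truth"],
        pixel_size_ha=cfg["pixel_size_ha"],
    )
    sig = default_signatures()
    scenes = generate_scene_series(
        truth, sig, cfg["n_scenes"], cfg["cloud_fraction_range"],
        seed=cfg["seed_scenes"], noise_sd=cfg["noise_sd"],
    )
    polygons = generate_training_polygons(
        truth, cfg["n_per_class"], polygon_size=cfg["polygon_size"],
        seed=cfg["seed_polygons"],
    )
    io.write_class_map(outdir / "truth.tif", truth)
    io.write_scene_series(outdir / "scenes", scenes)
    io.write_polygons(outdir / "polygons.geojson", polygons)
    write_manifest(outdir, "simulate", cfg, [],
                   [outdir / "truth.tif", outdir / "polygons.geojson",
                    outdir / "scenes" / "scene_index.csv"])


def stage_composite(cfg: dict, outdir: str | Path) -> None:
    """Filter, mask and median-composite the scene series; add indices."""
    outdir = Path(outdir)
    scenes = io.read_scene_series(_require(outdir / "scenes", "simulate"))
    stack = build_feature_stack(
        scenes, cfg["max_cloud_fraction"], pixel_size_ha=cfg["pixel_size_ha"]
    )
    layers = np.concatenate(
        [stack.features, stack.provenance[None].astype(np.float32)], axis=0
    )
    io.write_raster(
        outdir / "composite.tif", layers,
        band_names=stack.feature_names + ["provenance"],
        pixel_size_ha=cfg["pixel_size_ha"],
    )
    write_manifest(outdir, "composite", cfg,
                   [outdir / "scenes" / "scene_index.csv"],
                   [outdir / "composite.tif"])


def _read_composite(outdir: Path):
    from .compositing import BandSet, CompositeImage

    data, meta = io.read_raster(_require(outdir / "composite.tif", "composite"))
    return CompositeImage(
        bands=BandSet(data[:10]),
        ndvi=data[10],
        ndwi=data[11],
        provenance=data[12].astype(np.int32),
        pixel_size_ha=float(meta["pixel_size_ha"]),
    )


def stage_classify(cfg: dict, outdir: str | Path) -> None:
    """Train the forest on polygon pixels; predict the class map."""
    outdir = Path(outdir)
    stack = _read_composite(outdir)
    polygons = io.read_polygons(_require(outdir / "polygons.geojson", "simulate"))
    training = extract_training_pixels(stack, polygons)
    model = train_forest(
        training, n_trees=cfg["n_trees"],
        variables_per_split=cfg["variables_per_split"], seed=cfg["seed_model"],
    )
    predicted = predict_map(model, stack)
    ranking = variable_importance(model, training)
    (outdir / "model.json").write_text(model.to_json())
    io.write_class_map(outdir / "classmap.tif", predicted)
    io.write_table(
        outdir / "importance.csv",
        pd.DataFrame(
            {"feature": ranking.feature_names, "importance": ranking.scores}
        ).sort_values("importance", ascending=False, kind="stable"),
    )
    write_manifest(outdir, "classify", cfg,
                   [outdir / "composite.tif", outdir / "polygons.geojson"],
                   [outdir / "model.json", outdir / "classmap.tif",
                    outdir / "importance.csv"])


def stage_assess(cfg: dict, outdir: str | Path) -> None:
    """Stratified validation against the truth map; accuracy + unbiased areas."""
    outdir = Path(outdir)
    predicted = io.read_class_map(_require(outdir / "classmap.tif", "classify"))
    truth = io.read_class_map(_require(outdir / "truth.tif", "simulate"))
    mapped_areas = predicted.class_areas_ha()
    allocation = allocate_stratified_sample(
        mapped_areas, cfg["total_n"], cfg["min_per_stratum"],
        seed=cfg["seed_validation"],
    )
    points = draw_validation_points(predicted, allocation, seed=cfg["seed_validation"])
    reference = simulate_reference_labels(
        truth, points, error_rate=cfg["label_error_rate"],
        seed=cfg["seed_validation"] + 1,
    )
    map_labels = [code for _, code in points]
    codes = sorted(set(mapped_areas) | set(reference))
    cm = build_confusion_matrix(
        map_labels, reference,
        mapped_areas_ha={c: mapped_areas.get(c, 0.0) for c in codes},
        class_codes=codes,
    )
    report = accuracy_report(cm)
    estimate = unbiased_area_estimates(cm)

    io.write_table(outdir / "confusion.csv", cm.to_dataframe(), index=True)
    (outdir / "confusion.json").write_text(json.dumps({
        "class_names": cm.class_names,
        "counts": cm.counts.tolist(),
        "mapped_areas_ha": cm.mapped_areas_ha.tolist(),
    }, indent=2))
    acc_rows = [{"class": class_name(c), "ua_pct": u, "pa_pct": p}
                for c, u, p in zip(report.class_codes, report.ua, report.pa)]
    acc = pd.DataFrame(acc_rows)
    acc.attrs["oa"] = report.oa
    io.write_table(outdir / "accuracy.csv", acc)
    summary = pd.DataFrame([{
        "oa_counts_pct": report.oa,
        "oa_area_pct": area_based_overall_accuracy(cm),
        "n_points": cm.n,
    }])
    io.write_table(outdir / "accuracy_summary.csv", summary)
    io.write_table(outdir / "areas.csv", estimate.to_dataframe())
    write_manifest(outdir, "assess", cfg,
                   [outdir / "classmap.tif", outdir / "truth.tif"],
                   [outdir / "confusion.csv", outdir / "accuracy.csv",
                    outdir / "accuracy_summary.csv", outdir / "areas.csv"])


def stage_emissions(cfg: dict, outdir: str | Path,
                    areas_csv: str | Path | None = None) -> None:
    """Per-class and total CO2-C emissions from class areas and the EF table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if areas_csv is None:
        areas_path = outdir / "areas.csv"
        if areas_path.exists():
            df = io.read_table(areas_path)
            areas = dict(zip(df["class"], df["area_ha"].astype(float)))
        else:  # fall back to the packaged reference areas
            from .reference import load_reference_class_areas

            areas = load_reference_class_areas()
    else:
        df = io.read_table(areas_csv)
        areas = dict(zip(df["class"], df["area_ha"].astype(float)))
    efs = load_emission_factors(cfg.get("ef_table"))
    report = compute_emissions(areas, efs)
    io.write_table(outdir / "emissions.csv", report.table)
    (outdir / "emissions.txt").write_text(report.to_text() + "\n")
    totals = []
    for tier in ("T1", "T2"):
        if (report.table["tier"] == tier).any():
            tot, lo, hi = total_emissions(report, tier)
            totals.append({"tier": tier, "total_Mt": tot,
                           "naive_low_Mt": lo, "naive_high_Mt": hi})
    io.write_table(outdir / "emission_totals.csv", pd.DataFrame(totals))
    write_manifest(outdir, "emissions", cfg, [],
                   [outdir / "emissions.csv", outdir / "emission_totals.csv"])


STAGES = {
    "simulate": stage_simulate,
    "composite": stage_composite,
    "classify": stage_classify,
    "assess": stage_assess,
    "emissions": stage_emissions,
}


def run_all(cfg: dict, outdir: str | Path) -> None:
    """Run the full chain: simulate -> composite -> classify -> assess -> emissions."""
    for name in ("simulate", "composite", "classify", "assess", "emissions"):
        STAGES[name](cfg, outdir)
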