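"""End-to-end pipeline: simulate -> detect -> extract -> select -> evaluate.

Configuration is a nested mapping (YAML on disk) validated strictly: unknown
keys are rejected by name so typos cannot silently fall back to defaults.
Every random choice derives from the single top-level ``seed``, making the
emitted JSON metrics byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect as dt
from . import evaluate as ev
from . import features as ft
from . import select as sl
from . import synthscene as ss
from .io import write_feature_table

__all__ = ["default_config", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scene": {
        "n_scenes": 10,
        "width": 1024,
        "height": 1024,
        "class_counts": {c: 2 for c in ss.CLASS_LABELS},
        "background_level": 200.0,
        "background_gradient": 10.0,
        "noise_sd": 3.0,
        "bubble_count": 0,
    },
    "detect": {
        "min_radius": 20,
        "max_radius": 110,
        "radius_step": 2,
        "min_distance": 50,
        "accum_threshold": 0.35,
        "downscale": 2,          # half-resolution transform: ~8x faster,
                                 # center/radius quantization ~2 px
        "dedup_eps": 25.0,       # ~ 0.5 x smallest intact radius
        "dedup_min_pts": 1,
        "match_tolerance": 20.0,  # truth-matching radius for labeling, px
    },
    "features": {"core9_only": True},
    "select": {"run": False, "corr_threshold": 0.85, "n_repeats": 5},
    "evaluate": {
        "outer_folds": 5, "outer_seed": 42,
        "inner_folds": 5, "inner_seed": 1,
        "C_grid": [0.3, 1.0, 3.0, 10.0, 30.0],
        "gamma_grid": [0.003, 0.01, 0.03, "scale"],
        "class_weight_grid": [None, "balanced"],
        "inner_scoring": "macro_f1",
        "n_boot": 2000,
    },
}


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULT_CONFIG))


def validate_config(cfg: dict, schema: dict | None = None, path: str = ""
                    ) -> dict:
    """Merge a (possibly partial) config over the defaults, rejecting any
    key that the schema does not know."""
    schema = default_config() if schema is None else schema
    out = {}
    for key, val in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(schema[key], dict) and key != "class_counts":
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = validate_config(val, schema[key], path=f"{path}{key}.")
        else:
            out[key] = val
    for key, val in schema.items():
        out.setdefault(key, val)
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _match_label(det: dt.Detection, truth: ss.GroundTruth, tol: float
                 ) -> str | None:
    """Label a detection by the nearest ground-truth particle within
    max(tol, 0.5 x its radius) of the detected center."""
    best, best_d = None, np.inf
    for _, label, (tx, ty), tr in truth.records:
        d = float(np.hypot(det.center[0] - tx, det.center[1] - ty))
        if d < best_d:
            best, best_d = (label, tr), d
    if best is None or best_d > max(tol, 0.5 * best[1]):
        return None
    return best[0]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle.

    Emits ``features.csv`` (the extracted table), ``metrics.json`` (nested-CV
    summary, confusion matrix, curves), optionally ``selection.json``, and
    ``run_log.json`` (resolved config, seeds, versions, per-stage counters).
    Stage failures propagate with the stage name prefixed.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    log: dict = {"config": cfg, "versions": {
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
    }, "stages": {}}

    # ---- simulate ------------------------------------------------------
    try:
        scenes = []
        for i in range(cfg["scene"]["n_scenes"]):
            spec = ss.sample_scene(
                cfg["scene"]["class_counts"],
                seed=int(rng.integers(2**31)),
                width=cfg["scene"]["width"], height=cfg["scene"]["height"],
                background_level=cfg["scene"]["background_level"],
                background_gradient=cfg["scene"]["background_gradient"],
                noise_sd=cfg["scene"]["noise_sd"],
                bubble_count=cfg["scene"]["bubble_count"])
            img, truth = ss.render_scene(spec)
            scenes.append((f"scene_{i:03d}", img, truth))
        log["stages"]["simulate"] = {"n_scenes": len(scenes)}
    except Exception as e:
        raise RuntimeError(f"simulate stage failed: {e}") from e

    # ---- detect + crop -------------------------------------------------
    try:
        d = cfg["detect"]
        hp = dt.HoughParams(min_radius=d["min_radius"],
                            max_radius=d["max_radius"],
                            radius_step=d["radius_step"],
                            min_distance=d["min_distance"],
                            accum_threshold=d["accum_threshold"],
                            downscale=d["downscale"])
        crops: list[dt.ParticleCrop] = []
        n_det = n_unmatched = 0
        for image_id, img, truth in scenes:
            dets = dt.detect_circles(img, hp, image_id=image_id)
            dets = dt.dedup_detections(dets, eps=d["dedup_eps"],
                                       min_pts=d["dedup_min_pts"])
            n_det += len(dets)
            for det in dets:
                label = _match_label(det, truth, d["match_tolerance"])
                if label is None:
                    n_unmatched += 1
                    continue
                crop = dt.crop_particle(img, det)
                crops.append(dt.ParticleCrop(
                    pixels=crop.pixels, detection=det, label=label,
                    center_in_crop=crop.center_in_crop,
                    pad_fill=crop.pad_fill))
        log["stages"]["detect"] = {"n_detections": n_det,
                                   "n_labeled_crops": len(crops),
                                   "n_unmatched": n_unmatched}
    except Exception as e:
        raise RuntimeError(f"detect stage failed: {e}") from e

    # ---- extract -------------------------------------------------------
    try:
        rows, labels, n_flagged = [], [], 0
        for crop in crops:
            fv = ft.extract_all(crop)
            if "empty_mask" in fv.flags or not all(
                    np.isfinite(v) for v in fv.to_dict().values()):
                n_flagged += 1
                continue
            rows.append(fv.to_dict())
            labels.append(crop.label)
        table = pd.DataFrame(rows, columns=list(ft.FEATURES_11))
        table["label"] = labels
        table["slide_id"] = ""
        write_feature_table(table, outdir / "features.csv")
        log["stages"]["extract"] = {"n_rows": len(table),
                                    "n_flagged_excluded": n_flagged}
    except Exception as e:
        raise RuntimeError(f"extract stage failed: {e}") from e

    X11 = table[list(ft.FEATURES_11)]
    y = np.asarray(labels)

    # ---- select --------------------------------------------------------
    selection = None
    try:
        if cfg["select"]["run"]:
            corr, flagged = sl.correlation_screen(
                X11, threshold=cfg["select"]["corr_threshold"])
            vif_table = sl.vif(X11)
            selection = {
                "flagged_pairs": [(a, b, r) for a, b, r in flagged],
                "vif": {k: (v if np.isfinite(v) else None)
                        for k, v in vif_table["vif"].items()},
            }
            with open(outdir / "selection.json", "w") as fh:
                json.dump(selection, fh, indent=2, sort_keys=True)
        log["stages"]["select"] = {"ran": bool(cfg["select"]["run"])}
    except Exception as e:
        raise RuntimeError(f"select stage failed: {e}") from e

    # ---- evaluate ------------------------------------------------------
    try:
        e_ = cfg["evaluate"]
        spec = ev.CVSpec(
            outer_folds=e_["outer_folds"], outer_seed=e_["outer_seed"],
            inner_folds=e_["inner_folds"], inner_seed=e_["inner_seed"],
            C_grid=tuple(e_["C_grid"]),
            gamma_grid=tuple(e_["gamma_grid"]),
            class_weight_grid=tuple(e_["class_weight_grid"]),
            inner_scoring=e_["inner_scoring"])
        feats = list(ft.CORE9) if cfg["features"]["core9_only"] else list(ft.FEATURES_11)
        rep = ev.nested_cv(table[feats], y, spec)
        confusion = ev.oof_confusion(
            rep, class_order=tuple(c for c in ss.CLASS_LABELS
                                   if c in rep.classes))
        curves = ev.ovr_curves(rep, n_boot=e_["n_boot"], seed=cfg["seed"])
        metrics = {
            "summary": rep.summary(),
            "per_fold": [{"fold": f.fold, "params": f.params,
                          "macro_f1": f.macro_f1,
                          "balanced_accuracy": f.balanced_accuracy}
                         for f in rep.folds],
            "confusion_row_normalized": {
                "classes": list(confusion.index),
                "matrix": confusion.to_numpy().tolist()},
            "ovr": {str(c): {k: v for k, v in d.items()
                             if k not in ("roc", "pr")}
                    for c, d in curves["per_class"].items()},
            "micro_auprc": curves["micro_auprc"],
            "macro_auprc": curves["macro_auprc"],
        }
        log["stages"]["evaluate"] = {"fold_hash": rep.fold_hash}
    except Exception as e:
        raise RuntimeError(f"evaluate stage failed: {e}") from e

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=_default)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=_default)
    return {"metrics": metrics, "selection": selection, "log": log,
            "report": rep, "features": table}
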