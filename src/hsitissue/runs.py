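"""Run-directory artifacts: saving and loading cross-validation output.

A run directory holds one checkpoint per fold, per-image prediction maps
(compressed arrays plus rendered PNGs), per-fold loss curves (CSV), the
fold plan and the leakage audit (JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .evaluation import error_map, metrics_from_prediction, misclassified_count
from .io import AnnotationMask, Hypercube
from .model import PredictionMap, save_checkpoint
from .train import CVResult

PREDICTION_COLORS = {0: (40, 40, 40), 1: (0, 180, 0), 2: (150, 60, 180)}


def render_class_map(class_map: np.ndarray) -> np.ndarray:
    rgb = np.zeros((*class_map.shape, 3), dtype=np.uint8)
    for label, color in PREDICTION_COLORS.items():
        rgb[class_map == label] = color
    return rgb


def save_cv_run(result: CVResult, out_dir: str | Path,
                cohort: list[tuple[Hypercube, AnnotationMask]] | None = None) -> Path:
    """Write fold models, prediction maps, loss curves and the leakage audit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    masks = {c.animal_id: m for c, m in cohort} if cohort else {}

    losses = {}
    error_rows = []
    for fr in result.folds:
        save_checkpoint(fr.model, out / f"fold{fr.fold}_model.npz")
        losses[f"fold{fr.fold}"] = fr.loss_history
        for pm in fr.predictions:
            np.savez_compressed(out / f"{pm.animal_id}_prediction.npz",
                                class_map=pm.class_map, score_map=pm.score_map,
                                fold=np.array(fr.fold))
            Image.fromarray(render_class_map(pm.class_map)).save(
                out / f"{pm.animal_id}_prediction.png")
            if pm.animal_id in masks:
                labels = masks[pm.animal_id].labels
                Image.fromarray(error_map(labels, pm)).save(
                    out / f"{pm.animal_id}_errors.png")
                error_rows.append({
                    "animal_id": pm.animal_id, "fold": fr.fold,
                    "n_evaluated": int(pm.evaluated().sum()),
                    "n_misclassified": misclassified_count(labels, pm)})
    pd.DataFrame(losses).to_csv(out / "loss_curves.csv", index_label="epoch")
    if error_rows:
        pd.DataFrame(error_rows).to_csv(out / "error_counts.csv", index=False)
    with open(out / "leakage_audit.json", "w") as f:
        json.dump({"fold_assignment": result.fold_plan.fold_assignment,
                   "train_test_overlap": {str(k): v for k, v in
                                          result.leakage_audit.items()}}, f, indent=2)
    return out


def load_predictions(run_dir: str | Path) -> list[PredictionMap]:
    maps = []
    for path in sorted(Path(run_dir).glob("*_prediction.npz")):
        with np.load(path) as data:
            maps.append(PredictionMap(data["class_map"], data["score_map"],
                                      path.name.replace("_prediction.npz", "")))
    return maps


def write_report(per_image, cohort_metrics, out_dir: str | Path) -> Path:
    """Emit the cohort summary table and the per-image metric CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_metrics.to_frame().to_csv(out / "cohort_metrics.csv")
    rows = []
    for im in per_image:
        for cls, metrics in im.per_class.items():
            rows.append({"animal_id": im.animal_id, "positive_class": cls,
                         "n_evaluated": im.n_evaluated, **metrics})
    pd.DataFrame(rows).to_csv(out / "per_image_metrics.csv", index=False)
    return out
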