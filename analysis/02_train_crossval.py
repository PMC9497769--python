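"""Train the spectral-spatial CNN under leave-animal-out 5-fold CV.

Reads the cohort written by 01_generate_cohort.py, trains one model per
fold on patches from the 16 out-of-fold animals (class-weighted SGD), and
predicts every annotated pixel of the 4 held-out images per fold.  Writes
fold checkpoints, per-image prediction and error maps, loss curves and the
leakage audit proving that no animal crosses the train/test boundary.
"""

import argparse
import json
import time
from pathlib import Path

from hsitissue import TrainConfig, cross_validate
from hsitissue.io import read_cube, read_mask
from hsitissue.runs import save_cv_run


def load_cohort(data_dir: Path):
    cohort = []
    for cube_path in sorted(data_dir.glob("*.h5")):
        cube = read_cube(cube_path)
        mask = read_mask(cube_path.with_name(cube_path.stem + "_mask.png"),
                         expected_shape=cube.shape[:2])
        cohort.append((cube, mask))
    return cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/cv_run"))
    ap.add_argument("--epochs", type=int, default=25)
    ap.add_argument("--batch-size", type=int, default=1024)
    args = ap.parse_args()

    cohort = load_cohort(args.data)
    cfg = TrainConfig(epochs=args.epochs, batch_size=args.batch_size,
                      seed=args.seed)
    t0 = time.time()
    result = cross_validate(cohort, cfg, k=5, seed=args.seed)
    save_cv_run(result, args.out, cohort)

    with open(args.out / "leakage_audit.json") as f:
        audit = json.load(f)
    overlaps = [v for v in audit["train_test_overlap"].values() if v]
    print(f"trained 5 folds over {len(cohort)} animals in {time.time() - t0:.0f}s")
    print(f"leakage audit: {'CLEAN' if not overlaps else overlaps} "
          f"(every fold's train/test animal intersection is empty)")
    for fr in result.folds:
        print(f"  fold {fr.fold}: loss {fr.loss_history[0]:.3f} -> "
              f"{fr.loss_history[-1]:.3f}, class weights "
              f"{ {c: round(w, 3) for c, w in fr.class_weights.items()} }")


if __name__ == "__main__":
    main()
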