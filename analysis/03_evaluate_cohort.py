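"""Score the cross-validation run: per-image metrics, macro-averaged table.

Computes sensitivity, specificity, F1, MCC and ROC AUC per image and per
class over the annotated support, then macro-averages at image level
(unweighted mean ± SD across the 20 images) into the cohort summary table.
"""

import argparse
from pathlib import Path

from hsitissue import macro_average, metrics_from_prediction
from hsitissue.io import read_cube, read_mask
from hsitissue.runs import load_predictions, write_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--run", type=Path, default=Path("results/cv_run"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    masks = {}
    for cube_path in sorted(args.data.glob("*.h5")):
        cube = read_cube(cube_path)
        masks[cube.animal_id] = read_mask(
            cube_path.with_name(cube_path.stem + "_mask.png"),
            expected_shape=cube.shape[:2]).labels

    per_image = [metrics_from_prediction(masks[pm.animal_id], pm)
                 for pm in load_predictions(args.run)]
    cohort = macro_average(per_image)
    write_report(per_image, cohort, args.out)

    print(f"macro-averaged metrics over {cohort.n_images} images "
          f"(mean ± SD at image level):")
    print(cohort.to_frame().to_string())
    excl = {c: {m: n for m, n in v.items() if n} for c, v in cohort.n_excluded.items()}
    if any(excl.values()):
        print(f"images excluded from some averages (undefined metric): {excl}")


if __name__ == "__main__":
    main()
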