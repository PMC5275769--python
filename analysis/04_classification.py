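"""Class prediction with nested leave-one-out cross-validation.

Runs all seven classifiers (CCP, BCCP, DLDA, nearest centroid, 1NN, 3NN,
linear SVM) with feature selection and significance-threshold optimization
embedded in every fold, on both cohorts; then trains a frozen CCP model on
the count cohort and validates it on an independent cohort drawn from the
same population.  Writes per-sample predictions, ROC points, and a summary
under results/classification/.
"""

from pathlib import Path

import pandas as pd

import oscc_mirna as om
from oscc_mirna.pipeline import preprocess

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def load(tag: str, platform: str) -> om.NormalizedMatrix:
    values = pd.read_csv(ROOT / "normalized" / f"{tag}_normalized.tsv",
                         sep="\t", index_col=0)
    values.index.name = None
    labels = om.read_labels(ROOT / "data" / f"{tag}_labels.tsv")
    return om.NormalizedMatrix(values=values, platform=platform, labels=labels)


def main() -> None:
    out = ROOT / "classification"
    out.mkdir(parents=True, exist_ok=True)

    for tag, platform in (("mirnaseq", "counts"), ("qpcr", "ct")):
        norm = load(tag, platform)
        rows = []
        for algo in om.ALGORITHMS:
            cv = om.loocv(norm, algorithm=algo)
            cv.predictions.to_csv(out / f"{tag}_{algo}_predictions.csv",
                                  index_label="sample")
            pd.DataFrame(cv.roc, columns=["fpr", "tpr"]).to_csv(
                out / f"{tag}_{algo}_roc.csv", index=False)
            rows.append({"algorithm": algo, "accuracy": cv.accuracy,
                         "sensitivity": cv.sensitivity,
                         "specificity": cv.specificity, "auc": cv.auc})
        summary = pd.DataFrame(rows)
        summary.to_csv(out / f"{tag}_summary.csv", index=False)
        mean_acc = summary["accuracy"].mean()
        print(f"{tag}: mean LOOCV accuracy over {len(rows)} algorithms "
              f"{mean_acc:.3f}; per-algorithm "
              + ", ".join(f"{r['algorithm']} {r['accuracy']:.2f}" for r in rows))

    # external validation: frozen model, independent cohort, same population
    cfg = om.SimulationConfig(n_tumor=20, n_normal=7, seed=SEED)
    train_matrix, _ = om.simulate_counts(cfg)
    model = om.train(preprocess(train_matrix).normalized, algorithm="CCP",
                     alpha=0.001)
    val_cfg = om.SimulationConfig(n_tumor=20, n_normal=10, seed=SEED)
    val_matrix, _ = om.simulate_counts(val_cfg, cohort_seed=SEED + 7)
    cv = om.external_validate(model, preprocess(val_matrix).normalized)
    cv.predictions.to_csv(out / "external_validation_predictions.csv",
                          index_label="sample")
    print(f"external validation (20 tumor + 10 normal, frozen CCP model): "
          f"accuracy {cv.accuracy:.3f}, AUC {cv.auc:.3f}")


if __name__ == "__main__":
    main()
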