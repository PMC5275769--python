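"""Normalize both cohorts to a reference sample over a housekeeping panel.

Excludes the red-blood-cell contamination markers, applies the platform
detection filter (≥40% nonzero for counts, >60% detected for Ct), selects
the lowest-variance universally detected miRNAs as the housekeeping panel
(up to 50 for counts, 40 for Ct), and scales every sample to the reference.
Writes normalized matrices and per-sample factors under results/normalized/.
"""

from pathlib import Path

import oscc_mirna as om
from oscc_mirna.pipeline import preprocess

ROOT = Path(__file__).resolve().parent.parent / "results"


def run(platform: str, expr: str, labels: str, tag: str) -> None:
    matrix = om.read_expression(ROOT / "data" / expr, platform,
                                labels_path=ROOT / "data" / labels)
    result = preprocess(matrix)
    out = ROOT / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    result.normalized.values.to_csv(out / f"{tag}_normalized.tsv", sep="\t",
                                    index_label="mirna")
    result.factors.rename("factor").to_csv(out / f"{tag}_factors.csv",
                                           index_label="sample")
    print(f"{tag}: reference sample {result.reference_sample}, "
          f"housekeeping panel of {len(result.housekeeping_set)}, "
          f"factor range {result.factors.min():.3g}..{result.factors.max():.3g}")


def main() -> None:
    run("counts", "mirnaseq_counts.tsv", "mirnaseq_labels.tsv", "mirnaseq")
    run("ct", "qpcr_ct.tsv", "qpcr_labels.tsv", "qpcr")


if __name__ == "__main__":
    main()
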