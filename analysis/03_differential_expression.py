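"""Differential expression: per-miRNA t-tests with BH-FDR, rank products,
and the q<0.007 / ≥2-fold signature gate.

Reads the normalized matrices, tests tumor vs normal per miRNA, adds the
rank-product permutation analysis for the qPCR cohort (the platform it was
used on), selects the stringent signature that feeds pathway analysis, and
reports how well it recovers the planted ground truth.
Writes DE tables and the signature under results/de/.
"""

import json
from pathlib import Path

import pandas as pd

import oscc_mirna as om

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def load(tag: str, platform: str) -> om.NormalizedMatrix:
    values = pd.read_csv(ROOT / "normalized" / f"{tag}_normalized.tsv",
                         sep="\t", index_col=0)
    values.index.name = None
    labels = om.read_labels(ROOT / "data" / f"{tag.split('_')[0]}_labels.tsv")
    return om.NormalizedMatrix(values=values, platform=platform, labels=labels)


def main() -> None:
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)

    for tag, platform in (("mirnaseq", "counts"), ("qpcr", "ct")):
        norm = load(tag, platform)
        de = om.two_class_test(norm)
        if platform == "ct":
            complete = norm.values.dropna()
            rp = om.rank_product(
                om.NormalizedMatrix(values=complete, platform="ct",
                                    labels=norm.labels),
                n_perm=1000, seed=SEED,
            )
            de = de.join(rp[["rp", "rp_p"]])
        de.to_csv(out / f"{tag}_de.csv", index_label="mirna")

        truth = json.loads((ROOT / "data" / f"{tag}_truth.json").read_text())
        planted = set(truth["de_mirnas"]) & set(norm.values.index)
        n_q10 = int((de["q"] < 0.10).sum())
        sig = om.select_signature(de, q_max=0.007, min_fold=2.0)
        (out / f"{tag}_signature.txt").write_text("\n".join(sig) + "\n")
        tp = len(set(sig) & planted)
        print(f"{tag}: {n_q10} miRNAs at FDR<0.10; signature (q<0.007, ≥2x) has "
              f"{len(sig)} miRNAs, recovering {tp}/{len(planted)} planted "
              f"({len(sig) - tp} spurious)")


if __name__ == "__main__":
    main()
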