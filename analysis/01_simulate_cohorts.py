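"""Generate the two study cohorts with known ground truth.

Writes a small-RNA-seq count cohort (20 tumor vs 7 normal brush samples) and
an RT-qPCR Ct cohort (20 tumor vs 17 normal), together with the matching
miRNA→target map, pathway gene sets (GMT), and the planted ground truth,
under results/data/.
"""

import json
from pathlib import Path

import oscc_mirna as om

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    seq_cfg = om.SimulationConfig(n_tumor=20, n_normal=7, seed=SEED)
    seq, seq_truth = om.simulate_counts(seq_cfg)
    om.write_expression(seq, OUT / "mirnaseq_counts.tsv")
    om.write_labels(seq.labels, OUT / "mirnaseq_labels.tsv")

    pcr_cfg = om.SimulationConfig(n_tumor=20, n_normal=17, seed=SEED + 1)
    pcr, pcr_truth = om.simulate_ct(pcr_cfg)
    om.write_expression(pcr, OUT / "qpcr_ct.tsv")
    om.write_labels(pcr.labels, OUT / "qpcr_labels.tsv")

    target_map, pathways, seq_truth = om.simulate_annotation(seq_cfg, seq_truth)
    om.write_target_map(target_map, OUT / "targets.tsv")
    om.write_gmt(pathways, OUT / "pathways.gmt")

    for name, truth in (("mirnaseq", seq_truth), ("qpcr", pcr_truth)):
        (OUT / f"{name}_truth.json").write_text(json.dumps(
            {"de_mirnas": truth.de_mirnas,
             "contamination_markers": list(truth.contamination_markers),
             "planted_pathway": truth.planted_pathway}, indent=2) + "\n")

    print(f"miRNAseq cohort: {seq.values.shape[0]} miRNAs x "
          f"{seq.values.shape[1]} samples, {len(seq_truth.de_mirnas)} planted DE")
    print(f"qPCR cohort: {pcr.values.shape[0]} miRNAs x "
          f"{pcr.values.shape[1]} samples, {len(pcr_truth.de_mirnas)} planted DE")
    print(f"annotation: {len(target_map)} miRNAs mapped, {len(pathways)} pathways, "
          f"planted pathway = {seq_truth.planted_pathway}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
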