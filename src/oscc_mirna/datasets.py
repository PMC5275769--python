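"""Small reference tables shipped with the package."""

from importlib import resources

import pandas as pd


def neurotrophin_targets() -> pd.DataFrame:
    """Published TCGA expression levels of neurotrophin-signaling genes
    targeted by the OSCC miRNA signature (tumor vs nontumor mean level,
    printed fold change, FDR).  Used to verify fold-change arithmetic and
    as the worked pathway-target example."""
    path = resources.files("oscc_mirna").joinpath("data/neurotrophin_targets_tcga.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col=0)
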