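"""Readers, writers, and in-memory containers for the pipeline's file formats.

The pipeline works on tab-separated expression matrices (miRNAs in rows,
samples in columns), two-column sample→class label tables, two-column
miRNA→target-gene maps, and GMT gene-set files.  Counts matrices hold
non-negative integers; Ct matrices hold positive reals with blanks or ``NA``
for undetected reactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

PLATFORM_COUNTS = "counts"
PLATFORM_CT = "ct"

#: Red-blood-cell miRNAs whose levels track blood contamination of the
#: sample rather than epithelial biology; excluded before analysis.
RBC_MARKERS = ("hsa-miR-451a", "hsa-miR-144-3p", "hsa-miR-144-5p")


@dataclass
class ExpressionMatrix:
    """A samples × miRNAs expression matrix with platform tag and labels.

    ``values`` is stored miRNAs-in-rows / samples-in-columns (the common
    expression-matrix dialect).  ``platform`` is ``"counts"`` (non-negative
    integer read counts) or ``"ct"`` (qPCR cycle thresholds, lower = more
    abundant, NaN = undetected).  ``labels`` maps sample id → class
    (``"tumor"`` / ``"normal"``) for the labeled subset of samples.
    """

    values: pd.DataFrame
    platform: str
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in (PLATFORM_COUNTS, PLATFORM_CT):
            raise FormatError(f"unknown platform {self.platform!r}")
        dup_rows = self.values.index[self.values.index.duplicated()]
        if len(dup_rows):
            raise FormatError(f"duplicate miRNA identifier {dup_rows[0]!r}")
        dup_cols = self.values.columns[self.values.columns.duplicated()]
        if len(dup_cols):
            raise FormatError(f"duplicate sample identifier {dup_cols[0]!r}")
        if self.platform == PLATFORM_COUNTS:
            arr = self.values.to_numpy()
            neg = np.argwhere(np.nan_to_num(arr) < 0)
            if neg.size:
                r, c = neg[0]
                raise FormatError(
                    "negative count at miRNA "
                    f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )
        unknown = set(self.labels) - set(self.values.columns)
        if unknown:
            raise FormatError(f"labeled sample {sorted(unknown)[0]!r} not in matrix")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected observations (count > 0 / Ct non-missing)."""
        if self.platform == PLATFORM_COUNTS:
            return self.values > 0
        return self.values.notna()

    def label_vector(self) -> pd.Series:
        """Class labels aligned to sample order; raises if any sample unlabeled."""
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no class label")
        return pd.Series([self.labels[s] for s in self.sample_ids], index=self.sample_ids)


@dataclass
class NormalizedMatrix:
    """Log2-scale expression (larger = more abundant) after normalization."""

    values: pd.DataFrame
    platform: str
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def label_vector(self) -> pd.Series:
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no class label")
        return pd.Series([self.labels[s] for s in self.sample_ids], index=self.sample_ids)


def read_expression(path, platform: str, labels_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (miRNAs in rows, first column = identifier).

    Blank cells and the literal ``NA`` become missing values (only legal on
    the ct platform).  Duplicated identifiers and negative counts raise
    :class:`FormatError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if platform == PLATFORM_COUNTS and df.isna().any().any():
        rc = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"missing count at miRNA {df.index[rc[0]]!r}, sample {df.columns[rc[1]]!r}"
        )
    labels = read_labels(labels_path) if labels_path is not None else {}
    return ExpressionMatrix(values=df.astype(float), platform=platform, labels=labels)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values
    if matrix.platform == PLATFORM_COUNTS:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="mirna", na_rep="NA")


def read_labels(path) -> dict[str, str]:
    """Two-column TSV (sample, class) → label map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"labels line {ln}: expected 2 fields, got {len(parts)}")
            out[parts[0]] = parts[1]
    return out


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, cls in labels.items():
            fh.write(f"{sample}\t{cls}\n")


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file into {pathway id: (description, gene set)}.

    Insertion order of pathways is preserved; duplicate genes within one
    line are collapsed.  A line with fewer than three fields is an error.
    """
    pathways: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {ln}: expected ≥3 tab-separated fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            pathways[name] = (desc, set(g for g in genes if g))
    if not pathways:
        logger.warning("GMT file %s contains no gene sets", path)
    return pathways


def write_gmt(pathways: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in pathways.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_target_map(path) -> dict[str, set[str]]:
    """Two-column TSV (miRNA, gene) → {miRNA: target gene set}."""
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"target map line {ln}: expected 2 fields")
            targets.setdefault(parts[0], set()).add(parts[1])
    if not targets:
        logger.warning("target map %s is empty", path)
    return targets


def write_target_map(targets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for mirna in targets:
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")
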