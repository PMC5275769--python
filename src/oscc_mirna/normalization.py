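"""Reference-sample normalization over a consistently detected miRNA panel.

Each sample is scaled (counts) or shifted (Ct) so that a housekeeping panel
of miRNAs detected in every sample agrees with a chosen reference sample.
The per-sample factor is the median over the panel of the value ratios
(counts) or Ct differences (ct) against the reference; the median is robust
to a few genuinely differential panel members.  Output is on a log2 scale
with larger values meaning more abundant on both platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PipelineError
from .io import PLATFORM_COUNTS, ExpressionMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

#: housekeeping panel sizes: 50 consistently detected miRNAs for sequencing
#: counts, 40 for the qPCR panel
DEFAULT_PANEL_SIZE = {"counts": 50, "ct": 40}


@dataclass
class NormalizationResult:
    normalized: NormalizedMatrix
    reference_sample: str
    housekeeping_set: list[str]
    #: per-sample scale factor (counts; reference = 1) or Ct shift (ct; reference = 0)
    factors: pd.Series


def universally_detected(matrix: ExpressionMatrix) -> pd.Index:
    """miRNAs detected (count > 0 / Ct present) in every sample."""
    det = matrix.detected()
    return matrix.values.index[det.all(axis=1)]


def detect_consistent_set(matrix: ExpressionMatrix, panel_size: int | None = None) -> list[str]:
    """Choose the housekeeping panel: the ``panel_size`` universally detected
    miRNAs with the lowest variance of log expression (ties broken by
    identifier).

    Raises :class:`PipelineError` reporting the achievable maximum when fewer
    than ``panel_size`` miRNAs are detected in all samples.
    """
    if panel_size is None:
        panel_size = DEFAULT_PANEL_SIZE[matrix.platform]
    universal = universally_detected(matrix)
    if len(universal) < panel_size:
        raise PipelineError(
            f"only {len(universal)} miRNAs are detected in every sample; "
            f"cannot build a panel of {panel_size}"
        )
    sub = matrix.values.loc[universal]
    if matrix.platform == PLATFORM_COUNTS:
        log_expr = np.log2(sub)
    else:
        log_expr = sub  # Ct already log-scale
    var = log_expr.var(axis=1, ddof=1)
    order = sorted(universal, key=lambda m: (var[m], m))
    return order[:panel_size]


def default_reference_sample(matrix: ExpressionMatrix) -> str:
    """Sample with the most detected miRNAs (ties → first in column order)."""
    det = matrix.detected().sum(axis=0)
    return str(det.idxmax())


def normalize_to_reference(
    matrix: ExpressionMatrix,
    reference: str | None = None,
    housekeeping: list[str] | None = None,
    panel_size: int | None = None,
    aggregator: str = "median",
    pseudocount: float = 1.0,
) -> NormalizationResult:
    """Normalize every sample to the reference via the housekeeping panel.

    Counts: factor_j = median_{i in panel}(x_ij / x_i,ref) and the normalized
    value is log2(x_ij / factor_j + pseudocount).  Ct: shift_j =
    median_{i in panel}(Ct_ij − Ct_i,ref) and the normalized value is
    −(Ct_ij − shift_j), so larger always means more abundant.
    """
    if reference is None:
        reference = default_reference_sample(matrix)
    if reference not in matrix.values.columns:
        raise PipelineError(f"reference sample {reference!r} not in matrix")
    if housekeeping is None:
        housekeeping = detect_consistent_set(matrix, panel_size)
    missing = [m for m in housekeeping if m not in matrix.values.index]
    if missing:
        raise PipelineError(f"housekeeping miRNA {missing[0]!r} absent from matrix")
    if aggregator not in ("median", "mean"):
        raise PipelineError(f"unknown aggregator {aggregator!r}")
    agg = np.nanmedian if aggregator == "median" else np.nanmean

    hk = matrix.values.loc[housekeeping]
    ref_col = hk[reference].to_numpy()
    if matrix.platform == PLATFORM_COUNTS:
        ratios = hk.to_numpy() / ref_col[:, None]
        factors = pd.Series(agg(ratios, axis=0), index=matrix.values.columns)
        factors[reference] = 1.0  # exact identity for the reference
        scaled = matrix.values / factors
        normalized = np.log2(scaled + pseudocount)
    else:
        diffs = hk.to_numpy() - ref_col[:, None]
        factors = pd.Series(agg(diffs, axis=0), index=matrix.values.columns)
        factors[reference] = 0.0
        normalized = -(matrix.values - factors)

    return NormalizationResult(
        normalized=NormalizedMatrix(
            values=normalized, platform=matrix.platform, labels=dict(matrix.labels)
        ),
        reference_sample=reference,
        housekeeping_set=list(housekeeping),
        factors=factors,
    )


def exclude_markers(
    matrix: ExpressionMatrix, exclusion: list[str] | tuple[str, ...]
) -> ExpressionMatrix:
    """Drop contamination-marker miRNAs (e.g. the RBC set) from the matrix.

    Identifiers absent from the matrix are ignored with a log line.
    """
    present = [m for m in exclusion if m in matrix.values.index]
    absent = [m for m in exclusion if m not in matrix.values.index]
    for m in absent:
        logger.warning("exclusion marker %s not present in matrix", m)
    if present:
        logger.info("excluding %d marker miRNAs: %s", len(present), ", ".join(present))
    return ExpressionMatrix(
        values=matrix.values.drop(index=present),
        platform=matrix.platform,
        labels=dict(matrix.labels),
    )
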