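"""Convenience drivers chaining the standard preprocessing steps."""

from __future__ import annotations

from .de import detection_filter
from .io import RBC_MARKERS, ExpressionMatrix
from .normalization import (
    DEFAULT_PANEL_SIZE,
    NormalizationResult,
    detect_consistent_set,
    exclude_markers,
    normalize_to_reference,
    universally_detected,
)


def preprocess(
    matrix: ExpressionMatrix,
    panel_size: int | None = None,
    min_detect_frac: float | None = None,
    exclusion: tuple[str, ...] = RBC_MARKERS,
    reference: str | None = None,
    aggregator: str = "median",
) -> NormalizationResult:
    """Contamination-marker exclusion → detection filter → normalization.

    The housekeeping panel is capped at the number of universally detected
    miRNAs the cohort actually provides (small cohorts with dropout may not
    support the full platform default of 50/40).
    """
    filtered = detection_filter(exclude_markers(matrix, list(exclusion)),
                                min_detect_frac)
    cap = panel_size if panel_size is not None else DEFAULT_PANEL_SIZE[matrix.platform]
    achievable = len(universally_detected(filtered))
    panel = detect_consistent_set(filtered, panel_size=min(cap, achievable))
    return normalize_to_reference(filtered, housekeeping=panel,
                                  reference=reference, aggregator=aggregator)
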