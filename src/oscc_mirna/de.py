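"""Per-miRNA differential expression between tumor and normal classes.

Covers the detection filter, two-sample t-tests with Benjamini–Hochberg FDR,
linear fold changes, the rank-product statistic with a label-permutation
p-value, and the signature-selection gate (FDR < 0.007 and ≥2-fold change)
used to pick the miRNA set submitted to pathway analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError
from .io import PLATFORM_COUNTS, ExpressionMatrix, NormalizedMatrix
from .simulate import TUMOR

#: default minimal detected fraction: counts keeps miRNAs with up to 60%
#: zeros (≥40% detected); qPCR requires detection in over 60% of samples
DEFAULT_MIN_DETECT_FRAC = {"counts": 0.40, "ct": 0.60}


def detection_filter(
    matrix: ExpressionMatrix, min_detect_frac: float | None = None
) -> ExpressionMatrix:
    """Drop miRNAs detected in too few samples.

    Counts platform retains detected fraction ≥ threshold ("up to 60% zero"
    at the default 0.40); ct platform retains fraction strictly > threshold
    ("detectable in over 60%" at the default 0.60).
    """
    if min_detect_frac is None:
        min_detect_frac = DEFAULT_MIN_DETECT_FRAC[matrix.platform]
    if not 0 <= min_detect_frac <= 1:
        raise PipelineError("min_detect_frac must lie in [0, 1]")
    frac = matrix.detected().mean(axis=1)
    if matrix.platform == PLATFORM_COUNTS:
        keep = frac >= min_detect_frac
    else:
        keep = frac > min_detect_frac
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        platform=matrix.platform,
        labels=dict(matrix.labels),
    )


def pooled_ttest(
    X: np.ndarray, in_a: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test of class a vs class b, NaN-aware.

    Returns ``(diff_of_means, t, p)`` per row.  Pooled variance by default
    (the classic class-comparison idiom); ``equal_var=False`` gives Welch.
    Rows with zero variance and zero mean difference get t = 0, p = 1.
    """
    A, B = X[:, in_a], X[:, ~in_a]
    n1 = np.sum(~np.isnan(A), axis=1)
    n2 = np.sum(~np.isnan(B), axis=1)
    if np.any(n1 + n2 < 3) or np.any(n1 < 1) or np.any(n2 < 1):
        raise PipelineError("each row needs ≥1 value per class and ≥3 values total")
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(A, axis=1)
        m2 = np.nanmean(B, axis=1)
        ss1 = np.nansum((A - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((B - m2[:, None]) ** 2, axis=1)
    diff = m1 - m2
    if equal_var:
        df = (n1 + n2 - 2).astype(float)
        sp2 = (ss1 + ss2) / df
        se = np.sqrt(np.maximum(sp2, 1e-300) * (1.0 / n1 + 1.0 / n2))
    else:
        v1 = ss1 / np.maximum(n1 - 1, 1)
        v2 = ss2 / np.maximum(n2 - 1, 1)
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(np.maximum(se2, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / np.maximum(n1 - 1, 1)
                + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
            )
        df = np.where(np.isfinite(df), df, 1.0)
    t = np.where(diff == 0, 0.0, diff / se)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return diff, t, p


def two_class_test(
    norm: NormalizedMatrix, labels: pd.Series | None = None, equal_var: bool = True
) -> pd.DataFrame:
    """Per-miRNA tumor-vs-normal t-test on normalized log2 values.

    On the counts platform a zero read count is a non-detection, not a
    measured level, so zeros are masked and each miRNA is tested on its
    detected values only (the same convention the detection filter uses).
    miRNAs with fewer than two detected values in a class get NaN statistics
    and are excluded from the BH adjustment.

    Returns a DataFrame indexed by miRNA with columns ``FC`` (linear
    tumor/normal ratio, 2^Δ of class means of log2 values), ``t``, ``p``,
    BH-adjusted ``q``, and ``detected_frac``.
    """
    if labels is None:
        labels = norm.label_vector()
    labels = labels.reindex(norm.sample_ids)
    in_tumor = (labels == TUMOR).to_numpy()
    if in_tumor.sum() < 2 or (~in_tumor).sum() < 2:
        raise PipelineError("two_class_test needs ≥2 samples in each class")
    X = norm.values.to_numpy(dtype=float)
    if norm.platform == PLATFORM_COUNTS:
        detected = X > 0
        X = np.where(detected, X, np.nan)
    else:
        detected = ~np.isnan(X)
    n1 = np.sum(detected[:, in_tumor], axis=1)
    n2 = np.sum(detected[:, ~in_tumor], axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    diff = np.full(X.shape[0], np.nan)
    t = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    q = np.full(X.shape[0], np.nan)
    if valid.any():
        diff[valid], t[valid], p[valid] = pooled_ttest(
            X[valid], in_tumor, equal_var=equal_var
        )
        q[valid] = bh_adjust(p[valid])
    return pd.DataFrame(
        {
            "FC": np.exp2(diff),
            "t": t,
            "p": p,
            "q": q,
            "detected_frac": detected.mean(axis=1),
        },
        index=norm.values.index,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_a: float, mean_b: float) -> float:
    """Linear fold change mean_a / mean_b (tumor over normal)."""
    if mean_b <= 0:
        raise PipelineError("fold change undefined: denominator mean must be > 0")
    if mean_a < 0:
        raise PipelineError("fold change undefined: numerator mean must be ≥ 0")
    return mean_a / mean_b


def rank_product(
    norm: NormalizedMatrix,
    labels: pd.Series | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided rank-product statistic with a permutation p-value.

    For every tumor×normal sample pair, miRNAs are ranked by the pairwise
    log-ratio; the statistic is the geometric mean of ranks across pairs,
    computed separately for up- (rank 1 = most up in tumor) and
    down-regulation.  The permutation p-value for each direction is
    (1 + #{permuted rp ≤ observed}) / (n_perm + 1) under label permutation;
    the reported ``rp``/``rp_p`` is the better direction with a Bonferroni
    ×2 for testing both, capped at 1.
    """
    if n_perm < 1:
        raise PipelineError("n_perm must be ≥ 1")
    if labels is None:
        labels = norm.label_vector()
    labels = labels.reindex(norm.sample_ids)
    in_tumor = (labels == TUMOR).to_numpy()
    n_t, n_n = int(in_tumor.sum()), int((~in_tumor).sum())
    if n_t < 1 or n_n < 1:
        raise PipelineError("rank_product needs ≥1 sample per class")
    X = norm.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PipelineError("rank_product requires complete values (filter or impute first)")

    rp_up, rp_down = _rank_products(X, in_tumor)
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    hits_up = np.ones(X.shape[0])
    hits_down = np.ones(X.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_t]] = True
        pu, pdn = _rank_products(X, mask)
        hits_up += pu <= rp_up
        hits_down += pdn <= rp_down
    p_up = hits_up / (n_perm + 1)
    p_down = hits_down / (n_perm + 1)
    use_up = p_up <= p_down
    rp = np.where(use_up, rp_up, rp_down)
    rp_p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    return pd.DataFrame(
        {"rp": rp, "rp_p": rp_p, "rp_up": rp_up, "rp_down": rp_down},
        index=norm.values.index,
    )


def _rank_products(X: np.ndarray, in_tumor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean ranks over all tumor×normal pairwise log-ratios."""
    T = X[:, in_tumor]
    N = X[:, ~in_tumor]
    # features × (n_t * n_n) grid of pairwise differences
    diffs = (T[:, :, None] - N[:, None, :]).reshape(X.shape[0], -1)
    ranks_down = stats.rankdata(diffs, axis=0)  # rank 1 = most down in tumor
    n_feat = X.shape[0]
    ranks_up = n_feat + 1 - ranks_down  # exact reversal; average ties symmetric
    rp_up = np.exp(np.mean(np.log(ranks_up), axis=1))
    rp_down = np.exp(np.mean(np.log(ranks_down), axis=1))
    return rp_up, rp_down


def select_signature(de: pd.DataFrame, q_max: float = 0.007, min_fold: float = 2.0) -> list[str]:
    """miRNAs with q < q_max and at least ``min_fold`` change in either
    direction, ordered by q ascending (ties by identifier)."""
    fc = de["FC"]
    keep = (de["q"] < q_max) & ((fc >= min_fold) | (fc <= 1.0 / min_fold))
    sub = de.loc[keep].sort_index().sort_values("q", kind="mergesort")
    return list(sub.index)
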