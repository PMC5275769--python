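"""Two-class prediction with feature selection nested inside cross-validation.

Implements the seven-classifier family of the class-comparison tradition:
compound covariate predictor (CCP), Bayesian compound covariate predictor
(BCCP), diagonal linear discriminant analysis (DLDA), nearest centroid (NC),
1- and 3-nearest neighbors, and a linear support vector machine.  Feature
selection (per-miRNA t-test at significance threshold α) and the choice of α
itself are re-done inside every leave-one-out fold, so the held-out sample
never influences the features, weights, or threshold used to predict it —
the "embedded" optimization that avoids selection bias.

All continuous scores are oriented so that larger means more tumor-like;
ties in class assignment break toward "normal".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn.svm import SVC

from .errors import PipelineError
from .de import pooled_ttest
from .io import PLATFORM_COUNTS, NormalizedMatrix
from .simulate import NORMAL, TUMOR

logger = logging.getLogger(__name__)

ALGORITHMS = ("CCP", "BCCP", "DLDA", "NC", "1NN", "3NN", "SVM")

#: candidate feature-selection significance thresholds for the embedded
#: optimization (the classic class-prediction grid)
DEFAULT_ALPHA_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)

_VAR_FLOOR = 1e-12
_SVM_COST = 1.0


@dataclass
class ClassifierModel:
    """A trained two-class model: selected features plus per-algorithm stats."""

    algorithm: str
    alpha: float
    features: list[str]
    #: per-feature t-statistics (CCP/BCCP only)
    weights: np.ndarray | None
    class_stats: dict
    priors: dict[str, float] = field(default_factory=lambda: {TUMOR: 0.5, NORMAL: 0.5})


@dataclass
class CVResult:
    """Per-sample predictions with summary accuracy and ROC."""

    predictions: pd.DataFrame  # index sample; columns true, predicted, score, alpha, n_features
    accuracy: float
    sensitivity: float
    specificity: float
    roc: np.ndarray  # (k, 2) array of (FPR, TPR) points
    auc: float
    fold_details: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# missing-value handling
#
# On the counts platform a zero is a non-detection; zeros are masked to NaN,
# feature selection runs on detected values, and classifiers impute missing
# entries with the per-feature mean of the training fold only (so a held-out
# sample's values never enter the imputation used to predict it).


def _masked(matrix, values: pd.DataFrame) -> np.ndarray:
    X = values.to_numpy(dtype=float)
    if isinstance(matrix, NormalizedMatrix) and matrix.platform == PLATFORM_COUNTS:
        X = np.where(X > 0, X, np.nan)
    return X


def _ttest_sel(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NaN-tolerant selection t-test: untestable rows get t = 0, p = 1."""
    det = ~np.isnan(X)
    n1 = det[:, y].sum(axis=1)
    n2 = det[:, ~y].sum(axis=1)
    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    t = np.zeros(X.shape[0])
    p = np.ones(X.shape[0])
    if valid.any():
        _, t[valid], p[valid] = pooled_ttest(X[valid], y)
    return t, p


def _fit_fold(X: np.ndarray, y: np.ndarray, idx: np.ndarray, tstats: np.ndarray,
              algorithm: str, priors: tuple[float, float] = (0.5, 0.5)) -> dict:
    """Impute the selected training rows and fit; stores the impute means."""
    sub = X[idx]
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(sub, axis=1)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    sub = np.where(np.isnan(sub), mu[:, None], sub)
    core = _fit_core(sub, y, algorithm, tstats[idx], priors)
    core["impute"] = mu
    return core


def _score_samples(core: dict, algorithm: str, Xte: np.ndarray) -> np.ndarray:
    mu = core.get("impute")
    if mu is not None and np.isnan(Xte).any():
        Xte = np.where(np.isnan(Xte), np.asarray(mu)[:, None], Xte)
    return _score_core(core, algorithm, Xte)


# ---------------------------------------------------------------------------
# feature selection


def select_features(
    train: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series | None = None,
    alpha: float = 0.01,
) -> tuple[list[str], np.ndarray]:
    """miRNAs with two-class t-test p < alpha on the training data only.

    Weights are the t-statistics.  If no miRNA passes, falls back to the
    single smallest-p miRNA so every classifier has at least one feature.
    """
    values = train.values if isinstance(train, NormalizedMatrix) else train
    if labels is None:
        if not isinstance(train, NormalizedMatrix):
            raise PipelineError("labels required when passing a bare DataFrame")
        labels = train.label_vector()
    labels = labels.reindex(values.columns)
    y = (labels == TUMOR).to_numpy()
    _check_classes(y)
    t, p = _ttest_sel(_masked(train, values), y)
    idx = _select_indices(p, alpha)
    return [values.index[i] for i in idx], t[idx]


def _select_indices(p: np.ndarray, alpha: float) -> np.ndarray:
    idx = np.flatnonzero(p < alpha)
    if idx.size == 0:
        idx = np.array([int(np.argmin(p))])
    return idx


def _check_classes(y: np.ndarray) -> None:
    if y.sum() < 1 or (~y).sum() < 1 or y.size < 3:
        raise PipelineError("training data needs both classes and ≥3 samples")


# ---------------------------------------------------------------------------
# core fits on arrays (features × samples); y True = tumor


def _fit_core(X: np.ndarray, y: np.ndarray, algorithm: str,
              tstats: np.ndarray, priors: tuple[float, float] = (0.5, 0.5)) -> dict:
    if algorithm in ("CCP", "BCCP"):
        c = tstats @ X
        mu_t, mu_n = c[y].mean(), c[~y].mean()
        core = {"w": tstats, "thr": 0.5 * (mu_t + mu_n),
                "sign": 1.0 if mu_t >= mu_n else -1.0,
                "mu": (mu_t, mu_n)}
        if algorithm == "BCCP":
            v_t = c[y].var(ddof=1) if y.sum() > 1 else 0.0
            v_n = c[~y].var(ddof=1) if (~y).sum() > 1 else 0.0
            core["var"] = (max(v_t, _VAR_FLOOR), max(v_n, _VAR_FLOOR))
            core["priors"] = priors
        return core
    if algorithm in ("DLDA", "NC"):
        mu_t = X[:, y].mean(axis=1)
        mu_n = X[:, ~y].mean(axis=1)
        core = {"mu_t": mu_t, "mu_n": mu_n}
        if algorithm == "DLDA":
            ss = np.sum((X[:, y] - mu_t[:, None]) ** 2, axis=1) + np.sum(
                (X[:, ~y] - mu_n[:, None]) ** 2, axis=1
            )
            df = max(X.shape[1] - 2, 1)
            core["var"] = np.maximum(ss / df, _VAR_FLOOR)
        return core
    if algorithm in ("1NN", "3NN"):
        k = int(algorithm[0])
        if k > y.size:
            raise PipelineError(f"{algorithm} needs at least {k} training samples")
        return {"X": X, "y": y, "k": k}
    if algorithm == "SVM":
        clf = SVC(kernel="linear", C=_SVM_COST)
        clf.fit(X.T, y)
        return {"coef": clf.coef_.ravel(), "intercept": float(clf.intercept_[0])}
    raise PipelineError(f"unknown algorithm {algorithm!r}")


def _score_core(core: dict, algorithm: str, X: np.ndarray) -> np.ndarray:
    """Continuous score per test column; larger = more tumor-like."""
    if algorithm == "CCP":
        c = core["w"] @ X
        return core["sign"] * (c - core["thr"])
    if algorithm == "BCCP":
        c = core["w"] @ X
        mu_t, mu_n = core["mu"]
        v_t, v_n = core["var"]
        pt, pn = core["priors"]
        log_t = -0.5 * np.log(2 * np.pi * v_t) - (c - mu_t) ** 2 / (2 * v_t) + np.log(pt)
        log_n = -0.5 * np.log(2 * np.pi * v_n) - (c - mu_n) ** 2 / (2 * v_n) + np.log(pn)
        m = np.maximum(log_t, log_n)
        post_t = np.exp(log_t - m) / (np.exp(log_t - m) + np.exp(log_n - m))
        return post_t - 0.5
    if algorithm == "DLDA":
        d_t = np.sum((X - core["mu_t"][:, None]) ** 2 / core["var"][:, None], axis=0)
        d_n = np.sum((X - core["mu_n"][:, None]) ** 2 / core["var"][:, None], axis=0)
        return d_n - d_t
    if algorithm == "NC":
        d_t = np.sqrt(np.sum((X - core["mu_t"][:, None]) ** 2, axis=0))
        d_n = np.sqrt(np.sum((X - core["mu_n"][:, None]) ** 2, axis=0))
        return d_n - d_t
    if algorithm in ("1NN", "3NN"):
        d = np.sqrt(
            np.sum((core["X"][:, :, None] - X[:, None, :]) ** 2, axis=0)
        )  # train × test
        order = np.argsort(d, axis=0, kind="stable")[: core["k"]]
        votes = core["y"][order].mean(axis=0)
        return votes - 0.5
    if algorithm == "SVM":
        return core["coef"] @ X + core["intercept"]
    raise PipelineError(f"unknown algorithm {algorithm!r}")


def _predict_from_score(score: np.ndarray) -> np.ndarray:
    # strict inequality: ties in score break toward "normal"
    return np.where(score > 0, TUMOR, NORMAL)


# ---------------------------------------------------------------------------
# public train / predict


def train(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series | None = None,
    algorithm: str = "CCP",
    alpha: float = 0.01,
    priors: dict[str, float] | None = None,
) -> ClassifierModel:
    """Select features at threshold ``alpha`` and fit one classifier."""
    if algorithm not in ALGORITHMS:
        raise PipelineError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if labels is None:
        if not isinstance(matrix, NormalizedMatrix):
            raise PipelineError("labels required when passing a bare DataFrame")
        labels = matrix.label_vector()
    labels = labels.reindex(values.columns)
    y = (labels == TUMOR).to_numpy()
    _check_classes(y)
    pri = priors or {TUMOR: 0.5, NORMAL: 0.5}
    if abs(pri[TUMOR] + pri[NORMAL] - 1.0) > 1e-9:
        raise PipelineError("class priors must sum to 1")
    X = _masked(matrix, values)
    t, p = _ttest_sel(X, y)
    idx = _select_indices(p, alpha)
    core = _fit_fold(X, y, idx, t, algorithm, (pri[TUMOR], pri[NORMAL]))
    features = [values.index[i] for i in idx]
    weights = t[idx] if algorithm in ("CCP", "BCCP") else None
    return ClassifierModel(
        algorithm=algorithm, alpha=alpha, features=features,
        weights=weights, class_stats=core, priors=pri,
    )


def predict(model: ClassifierModel, matrix: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Apply a frozen model; returns per-sample predicted class and score."""
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    missing = [f for f in model.features if f not in values.index]
    if missing:
        raise PipelineError(f"model feature {missing[0]!r} missing from matrix")
    X = _masked(matrix, values.loc[model.features])  # platform-aware zero masking
    score = _score_samples(model.class_stats, model.algorithm, X)
    return pd.DataFrame(
        {"predicted": _predict_from_score(score), "score": score},
        index=values.columns,
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation with embedded alpha optimization


def loocv(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series | None = None,
    algorithm: str = "CCP",
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
) -> CVResult:
    """Nested leave-one-out cross-validation.

    For each held-out sample, the significance threshold α is chosen from
    ``alpha_grid`` by an inner leave-one-out on the remaining n−1 samples
    (ties → smaller α); features and the classifier are then re-fit on those
    n−1 samples only and the held-out sample is predicted.  The held-out
    sample never influences its own feature selection, α, or weights.
    """
    if algorithm not in ALGORITHMS:
        raise PipelineError(f"unknown algorithm {algorithm!r}")
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if labels is None:
        if not isinstance(matrix, NormalizedMatrix):
            raise PipelineError("labels required when passing a bare DataFrame")
        labels = matrix.label_vector()
    labels = labels.reindex(values.columns)
    y = (labels == TUMOR).to_numpy()
    n = y.size
    if n < 4:
        raise PipelineError("leave-one-out cross-validation needs n ≥ 4")
    if y.sum() < 1 or (~y).sum() < 1:
        raise PipelineError("both classes must be present")
    grid = tuple(sorted(alpha_grid))
    if not grid:
        raise PipelineError("alpha_grid must be non-empty")
    X = _masked(matrix, values)

    preds, scores, alphas, nfeat, details = [], [], [], [], []
    for j in range(n):
        tr = np.ones(n, dtype=bool)
        tr[j] = False
        alpha_j = _choose_alpha(X[:, tr], y[tr], algorithm, grid)
        t, p = _ttest_sel(X[:, tr], y[tr])
        idx = _select_indices(p, alpha_j)
        core = _fit_fold(X[:, tr], y[tr], idx, t, algorithm)
        s = float(_score_samples(core, algorithm, X[idx][:, [j]])[0])
        scores.append(s)
        preds.append(TUMOR if s > 0 else NORMAL)
        alphas.append(alpha_j)
        nfeat.append(idx.size)
        details.append(
            {"sample": values.columns[j], "alpha": alpha_j,
             "features": [values.index[i] for i in idx]}
        )

    truth = np.where(y, TUMOR, NORMAL)
    predictions = pd.DataFrame(
        {"true": truth, "predicted": preds, "score": scores,
         "alpha": alphas, "n_features": nfeat},
        index=values.columns,
    )
    return _summarize(predictions, details)


def _choose_alpha(X: np.ndarray, y: np.ndarray, algorithm: str,
                  grid: tuple[float, ...]) -> float:
    """Inner leave-one-out accuracy per α; smallest α among the best."""
    n = y.size
    correct = np.zeros(len(grid))
    valid = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        yt = y[tr]
        if yt.sum() < 1 or (~yt).sum() < 1 or yt.size < 3:
            continue
        if algorithm in ("1NN", "3NN") and yt.size < int(algorithm[0]):
            continue
        valid += 1
        t, p = _ttest_sel(X[:, tr], yt)
        for g, alpha in enumerate(grid):
            idx = _select_indices(p, alpha)
            core = _fit_fold(X[:, tr], yt, idx, t, algorithm)
            s = float(_score_samples(core, algorithm, X[idx][:, [i]])[0])
            correct[g] += (s > 0) == y[i]
    if valid == 0:
        # no informative inner split: default to the most inclusive threshold
        return grid[-1]
    best = np.flatnonzero(correct == correct.max())
    return grid[best[0]]


def _summarize(predictions: pd.DataFrame, details: list[dict] | None = None) -> CVResult:
    truth = predictions["true"].to_numpy()
    pred = predictions["predicted"].to_numpy()
    scores = predictions["score"].to_numpy(dtype=float)
    accuracy = float(np.mean(pred == truth))
    is_t = truth == TUMOR
    sensitivity = float(np.mean(pred[is_t] == TUMOR)) if is_t.any() else float("nan")
    specificity = float(np.mean(pred[~is_t] == NORMAL)) if (~is_t).any() else float("nan")
    roc, auc = roc_curve(scores, truth)
    return CVResult(
        predictions=predictions, accuracy=accuracy, sensitivity=sensitivity,
        specificity=specificity, roc=roc, auc=auc, fold_details=details or [],
    )


# ---------------------------------------------------------------------------
# ROC and external validation


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and the trapezoidal AUC.

    The AUC equals the normalized Mann–Whitney concordance count of
    tumor-vs-normal score pairs (ties counted 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise PipelineError("scores must be finite")
    y = labels == TUMOR
    if y.all() or not y.any():
        raise PipelineError("both classes must be present to build a ROC curve")
    fpr, tpr, _ = _skmetrics.roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def external_validate(
    model: ClassifierModel,
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series | None = None,
) -> CVResult:
    """Apply a frozen model to an independent cohort (no re-selection/fitting)."""
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if labels is None:
        if not isinstance(matrix, NormalizedMatrix):
            raise PipelineError("labels required when passing a bare DataFrame")
        labels = matrix.label_vector()
    labels = labels.reindex(values.columns)
    out = predict(model, matrix)
    predictions = pd.DataFrame(
        {"true": labels.to_numpy(), "predicted": out["predicted"].to_numpy(),
         "score": out["score"].to_numpy(),
         "alpha": model.alpha, "n_features": len(model.features)},
        index=values.columns,
    )
    return _summarize(predictions)


# ---------------------------------------------------------------------------
# JSON (de)serialization for --model-file round trips


def model_to_json(model: ClassifierModel) -> str:
    stats = {}
    for k, v in model.class_stats.items():
        if isinstance(v, np.ndarray):
            stats[k] = {"__array__": v.tolist()}
        elif isinstance(v, tuple):
            stats[k] = list(v)
        else:
            stats[k] = v
    return json.dumps(
        {
            "algorithm": model.algorithm,
            "alpha": model.alpha,
            "features": model.features,
            "weights": None if model.weights is None else list(map(float, model.weights)),
            "class_stats": stats,
            "priors": model.priors,
        },
        indent=2,
    )


def model_from_json(text: str) -> ClassifierModel:
    obj = json.loads(text)
    stats = {}
    for k, v in obj["class_stats"].items():
        if isinstance(v, dict) and "__array__" in v:
            stats[k] = np.asarray(v["__array__"], dtype=float)
        elif isinstance(v, list):
            stats[k] = tuple(v)
        else:
            stats[k] = v
    weights = obj["weights"]
    return ClassifierModel(
        algorithm=obj["algorithm"],
        alpha=obj["alpha"],
        features=list(obj["features"]),
        weights=None if weights is None else np.asarray(weights, dtype=float),
        class_stats=stats,
        priors={k: float(v) for k, v in obj["priors"].items()},
    )
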