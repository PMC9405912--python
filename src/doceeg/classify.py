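"""Step-2 outcome classification: stepwise diagonal LDA with
leave-one-subject-out cross-validation, plus a logistic-regression control.

The discriminant is the "diagLinear" rule: both classes share one pooled
*diagonal* covariance estimate (feature correlations are discounted
entirely), class priors are the training-fold class frequencies, and no
coefficient thresholding is applied. Feature standardization and priors
are recomputed inside every training fold, so no information leaks from
the held-out subject. The positive class is the *nonimproved* outcome:
sensitivity is the fraction of nonimproved patients correctly flagged.

"Stepwise" feature selection is an exhaustive search over every non-empty
subset of the candidate features (15 subsets for the four headline
biomarkers), ranked by LOO accuracy with ties broken by balanced
accuracy, then parsimony, then lexicographic order.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "nonimproved"
NEGATIVE_CLASS = "improved"


class SmallSampleError(RuntimeError):
    """A training fold would contain a class with fewer than 2 members."""


@dataclass
class ClassifierReport:
    feature_subset: tuple[str, ...]
    confusion: np.ndarray  # [[TP, FN], [FP, TN]] with positive = nonimproved
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    precision: float
    roc_points: list[tuple[float, float]]
    per_fold_predictions: list[dict] = field(default_factory=list)
    model: str = "diagLinear LDA"

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "features": list(self.feature_subset),
            "confusion": {"tp": int(self.confusion[0, 0]),
                          "fn": int(self.confusion[0, 1]),
                          "fp": int(self.confusion[1, 0]),
                          "tn": int(self.confusion[1, 1])},
            "accuracy": round(self.accuracy, 4),
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "balanced_accuracy": round(self.balanced_accuracy, 4),
            "precision": round(self.precision, 4),
            "roc_points": [[round(f, 4), round(t, 4)] for f, t in self.roc_points],
        }


def _report_from_predictions(subset, y_true, y_pred, scores,
                             per_fold, model) -> ClassifierReport:
    pos = y_true == POSITIVE_CLASS
    pred_pos = y_pred == POSITIVE_CLASS
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    n = tp + fn + fp + tn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return ClassifierReport(
        feature_subset=tuple(subset),
        confusion=np.array([[tp, fn], [fp, tn]]),
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        precision=prec,
        roc_points=_roc_points(pos.astype(int), scores),
        per_fold_predictions=per_fold,
        model=model,
    )


def _roc_points(y_pos: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    """ROC curve from pooled LOO discriminant scores (threshold sweep)."""
    order = np.argsort(-scores, kind="stable")
    y = y_pos[order]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int(len(y) - y.sum()), 1)
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    points = [(0.0, 0.0)]
    # collapse tied scores so the curve is a function of the threshold
    s = scores[order]
    boundary = np.nonzero(np.diff(s))[0].tolist() + [len(s) - 1]
    for i in boundary:
        points.append((fps[i] / n_neg, tps[i] / n_pos))
    return points


def _validate_table(ft: pd.DataFrame, subset, label_col: str) -> None:
    if not len(subset):
        raise ConfigurationError("feature subset must be non-empty")
    missing = [c for c in subset if c not in ft.columns]
    if missing:
        raise ConfigurationError(f"features missing from table: {missing}")
    if ft[list(subset)].isna().any().any():
        raise ConfigurationError("feature table contains missing values")
    classes = ft[label_col].unique()
    if len(classes) < 2:
        raise ConfigurationError("single-class input: both outcomes required")


def _loo_folds(X: np.ndarray, y: np.ndarray):
    n = len(y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        for cls in (POSITIVE_CLASS, NEGATIVE_CLASS):
            if (ytr == cls).sum() < 2:
                raise SmallSampleError(
                    f"training fold {i} leaves class {cls!r} with < 2 members"
                )
        Xtr = X[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        yield i, (Xtr - mu) / sd, ytr, (X[i] - mu) / sd


def _diag_lda_score(Xtr: np.ndarray, ytr: np.ndarray,
                    x: np.ndarray) -> float:
    """Positive-minus-negative discriminant score of the diagLinear rule."""
    pos = ytr == POSITIVE_CLASS
    mu_p, mu_n = Xtr[pos].mean(axis=0), Xtr[~pos].mean(axis=0)
    n = len(ytr)
    # pooled within-class diagonal variance (shared by both classes)
    ss = ((Xtr[pos] - mu_p) ** 2).sum(axis=0) + ((Xtr[~pos] - mu_n) ** 2).sum(axis=0)
    var = ss / (n - 2)
    var = np.where(var > 0, var, 1e-12)
    prior_p = pos.sum() / n
    d_p = -0.5 * np.sum((x - mu_p) ** 2 / var) + np.log(prior_p)
    d_n = -0.5 * np.sum((x - mu_n) ** 2 / var) + np.log(1.0 - prior_p)
    return float(d_p - d_n)


def lda_loo(ft: pd.DataFrame, subset, label_col: str = "outcome"
            ) -> ClassifierReport:
    """Leave-one-subject-out diagonal LDA over the given feature subset."""
    _validate_table(ft, subset, label_col)
    X = ft[list(subset)].to_numpy(float)
    y = ft[label_col].to_numpy()
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=object)
    per_fold = []
    for i, Xtr, ytr, x in _loo_folds(X, y):
        s = _diag_lda_score(Xtr, ytr, x)
        scores[i] = s
        preds[i] = POSITIVE_CLASS if s > 0 else NEGATIVE_CLASS
        per_fold.append({"index": int(i), "true": str(y[i]),
                         "predicted": str(preds[i]), "score": float(s)})
    return _report_from_predictions(subset, y, preds, scores, per_fold,
                                    "diagLinear LDA")


def logistic_control(ft: pd.DataFrame, subset, label_col: str = "outcome",
                     ridge_penalty: float = 1e-4) -> ClassifierReport:
    """Same LOO protocol with a maximum-likelihood logistic model.

    Perfect separation (or non-convergence) in a training fold falls back
    to a ridge-penalized fit with the given penalty, logged as a warning.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    _validate_table(ft, subset, label_col)
    X = ft[list(subset)].to_numpy(float)
    y = ft[label_col].to_numpy()
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=object)
    per_fold = []
    for i, Xtr, ytr, x in _loo_folds(X, y):
        ybin = (ytr == POSITIVE_CLASS).astype(int)
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(Xtr, ybin)
                separated = bool((model.predict(Xtr) == ybin).all()
                                 and np.abs(model.coef_).max() > 1e3)
            except ConvergenceWarning:
                separated = True
        if separated:
            logger.warning("fold %d: separation detected, ridge fallback", i)
            model = LogisticRegression(C=1.0 / ridge_penalty, solver="lbfgs",
                                       max_iter=500)
            model.fit(Xtr, ybin)
        s = float(model.decision_function(x[None, :])[0])
        scores[i] = s
        preds[i] = POSITIVE_CLASS if s > 0 else NEGATIVE_CLASS
        per_fold.append({"index": int(i), "true": str(y[i]),
                         "predicted": str(preds[i]), "score": float(s)})
    return _report_from_predictions(subset, y, preds, scores, per_fold,
                                    "logistic regression")


def stepwise_search(ft: pd.DataFrame, candidates,
                    label_col: str = "outcome",
                    mode: str = "exhaustive"
                    ) -> tuple[ClassifierReport, list[dict]]:
    """Best feature subset by LOO accuracy over all non-empty subsets.

    Returns the winning report and the full ranking. Pools larger than
    10 candidates must use ``mode="greedy"`` (forward selection).
    """
    candidates = list(candidates)
    if not 1 <= len(candidates):
        raise ConfigurationError("need at least one candidate feature")
    if len(candidates) > 10 and mode == "exhaustive":
        raise ConfigurationError(
            "more than 10 candidates: exhaustive search refused, "
            "use mode='greedy'"
        )
    if mode == "exhaustive":
        subsets = [c for r in range(1, len(candidates) + 1)
                   for c in itertools.combinations(candidates, r)]
    elif mode == "greedy":
        subsets = _greedy_path(ft, candidates, label_col)
    else:
        raise ConfigurationError(f"unknown search mode {mode!r}")

    results = [(sub, lda_loo(ft, sub, label_col=label_col)) for sub in subsets]
    results.sort(key=lambda item: (-item[1].accuracy,
                                   -item[1].balanced_accuracy,
                                   len(item[0]), item[0]))
    ranking = [{"features": list(sub), "accuracy": round(rep.accuracy, 4),
                "balanced_accuracy": round(rep.balanced_accuracy, 4)}
               for sub, rep in results]
    return results[0][1], ranking


def _greedy_path(ft, candidates, label_col):
    chosen: list[str] = []
    path = []
    remaining = list(candidates)
    while remaining:
        best = max(remaining, key=lambda c: lda_loo(
            ft, chosen + [c], label_col=label_col).accuracy)
        chosen.append(best)
        remaining.remove(best)
        path.append(tuple(chosen))
    return path


def metrics_from_rates(sensitivity: float, specificity: float,
                       n_pos: int, n_neg: int
                       ) -> tuple[float, float, float]:
    """(accuracy, balanced accuracy, precision) from printed rates and counts.

    TP and TN are recovered by rounding rate * count to the nearest
    integer, matching how published percentages arise from confusion
    counts.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ConfigurationError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ConfigurationError("class counts must be positive")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    accuracy = (tp + tn) / (n_pos + n_neg)
    balanced = (sensitivity + specificity) / 2.0
    fp = n_neg - tn
    if tp + fp == 0:
        raise ConfigurationError("no positive predictions: precision undefined")
    precision = tp / (tp + fp)
    return float(accuracy), float(balanced), float(precision)


def permutation_null_accuracy(ft: pd.DataFrame, subset,
                              n_permutations: int = 200,
                              label_col: str = "outcome",
                              seed: int | None = 0) -> np.ndarray:
    """LOO accuracies under random label permutation (chance distribution)."""
    rng = np.random.default_rng(seed)
    y = ft[label_col].to_numpy()
    out = []
    table = ft.copy()
    for _ in range(n_permutations):
        table[label_col] = rng.permutation(y)
        try:
            out.append(lda_loo(table, subset, label_col=label_col).accuracy)
        except SmallSampleError:
            continue
    return np.array(out)
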