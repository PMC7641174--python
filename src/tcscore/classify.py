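"""Diagnostic-model pipeline over the TCS feature matrix.

Stages mirror a conventional biomarker-panel workflow on a small cohort:

1. Welch's unequal-variance t-test per V-J feature shrinks the universe
   to the combinations that differ between the two classes.
2. Random-forest mean-decrease-in-impurity importance picks the final
   panel (default 13 features, 1000 trees).
3. A Gaussian naive-Bayes model over the panel produces the per-sample
   posterior of the positive class.
4. Evaluation: leave-one-out cross-validation, confusion statistics at a
   0.5 posterior threshold, ROC/AUC, and unsupervised average-linkage
   clustering of the samples on z-scored panel features.

By default the panel is selected once on the full training cohort and
held fixed inside the LOOCV folds; a nested, leak-free mode that
re-selects inside every fold is available (``nested=True``) and is the
right null-calibrated choice when the selection itself is under test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import norm, t as t_dist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .errors import ConfigurationError, DataError
from .tcs import TCSFeatureMatrix

POSITIVE_CLASS = "GO"
VAR_FLOOR = 1e-9


def _two_groups(labels: pd.Series, positive: str) -> tuple[str, str]:
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected exactly 2 classes, got {classes}")
    if positive not in classes:
        raise DataError(f"positive class {positive!r} absent from labels {classes}")
    negative = classes[0] if classes[1] == positive else classes[1]
    return positive, negative


# ---------------------------------------------------------------------------
# stage 1: Welch filter


def welch_test(matrix: pd.DataFrame, labels: pd.Series, positive: str = POSITIVE_CLASS) -> pd.DataFrame:
    """Per-feature Welch t statistic, Welch-Satterthwaite dof and two-sided p.

    Degenerate features (both group variances zero) get t = 0, p = 1 when
    the group means agree and p = 0 (infinite t) when they differ.
    """
    pos, neg = _two_groups(labels, positive)
    x1 = matrix.loc[labels == pos].to_numpy(float)
    x2 = matrix.loc[labels == neg].to_numpy(float)
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise DataError("Welch test needs n >= 2 per class")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * t_dist.sf(np.abs(t), dof)
    degenerate = se2 == 0.0
    equal_means = degenerate & (m1 == m2)
    diff_means = degenerate & (m1 != m2)
    t[equal_means], p[equal_means], dof[equal_means] = 0.0, 1.0, n1 + n2 - 2
    t[diff_means] = np.sign(m1 - m2)[diff_means] * np.inf
    p[diff_means], dof[diff_means] = 0.0, n1 + n2 - 2
    return pd.DataFrame({"t": t, "dof": dof, "p": p}, index=matrix.columns)


def welch_filter(
    matrix: pd.DataFrame,
    labels: pd.Series,
    mode: str = "p_threshold",
    alpha: float = 0.05,
    top_n: int | None = None,
    min_keep: int = 0,
    positive: str = POSITIVE_CLASS,
) -> tuple[pd.DataFrame, list[str]]:
    """Shrink the feature universe: keep p < alpha, or the top_n smallest p.

    ``min_keep`` guarantees a floor: if fewer than min_keep features pass
    the threshold, the min_keep smallest-p features are kept instead.
    """
    result = welch_test(matrix, labels, positive)
    if mode == "p_threshold":
        kept = result.index[result["p"] < alpha]
        if len(kept) < min_keep:
            kept = result.sort_values(["p", "t"]).index[:min_keep]
    elif mode == "top_n":
        if top_n is None or top_n < 1:
            raise ConfigurationError("top_n mode needs a positive top_n")
        kept = result.sort_values(["p", "t"]).index[:top_n]
    else:
        raise ConfigurationError(f"unknown welch_filter mode: {mode!r}")
    # keep the matrix column order for determinism
    filtered = [c for c in matrix.columns if c in set(kept)]
    return result, filtered


# ---------------------------------------------------------------------------
# stage 2: random-forest importance selection


@dataclass(frozen=True)
class SelectionResult:
    filtered: tuple[str, ...]
    selected: tuple[str, ...]
    importances: pd.Series
    seed: int


def rf_importance_select(
    matrix: pd.DataFrame,
    labels: pd.Series,
    filtered: Sequence[str],
    n_trees: int = 1000,
    k: int = 13,
    seed: int = 0,
) -> SelectionResult:
    """Top-k features by random-forest impurity importance; ties broken by VJ key."""
    if not len(filtered):
        raise DataError("empty filtered feature set")
    if k > len(filtered):
        raise ConfigurationError(f"k={k} exceeds the {len(filtered)} filtered features")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(matrix[list(filtered)].to_numpy(float), labels.to_numpy())
    importances = pd.Series(rf.feature_importances_, index=list(filtered), name="importance")
    order = sorted(importances.index, key=lambda f: (-importances[f], f))
    return SelectionResult(
        filtered=tuple(filtered),
        selected=tuple(order[:k]),
        importances=importances,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stage 3: Gaussian naive Bayes


@dataclass
class NBModel:
    """Gaussian naive Bayes: class priors plus per-feature class-conditional
    means and (floored) variances, serializable to JSON."""

    features: list[str]
    classes: list[str]
    priors: dict[str, float]
    means: dict[str, list[float]]  # class -> per-feature means
    variances: dict[str, list[float]]
    positive: str = POSITIVE_CLASS

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        return cls(**json.loads(Path(path).read_text()))


def nb_train(
    matrix: pd.DataFrame,
    labels: pd.Series,
    positive: str = POSITIVE_CLASS,
    var_floor: float = VAR_FLOOR,
) -> NBModel:
    """Fit class priors and per-feature Gaussian class-conditionals."""
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise DataError("naive Bayes training needs both classes present")
    priors, means, variances = {}, {}, {}
    for cls_label in classes:
        x = matrix.loc[labels == cls_label].to_numpy(float)
        priors[cls_label] = x.shape[0] / len(labels)
        means[cls_label] = x.mean(axis=0).tolist()
        ddof = 1 if x.shape[0] > 1 else 0
        v = np.maximum(x.var(axis=0, ddof=ddof), var_floor)
        variances[cls_label] = v.tolist()
    return NBModel(
        features=list(matrix.columns),
        classes=list(classes),
        priors=priors,
        means=means,
        variances=variances,
        positive=positive,
    )


def nb_predict(model: NBModel, x: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Posterior probability of the positive class for each row of x."""
    if isinstance(x, pd.DataFrame):
        x = x[model.features].to_numpy(float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    log_post = np.empty((x.shape[0], len(model.classes)))
    for j, cls_label in enumerate(model.classes):
        mu = np.asarray(model.means[cls_label])
        var = np.asarray(model.variances[cls_label])
        log_post[:, j] = np.log(model.priors[cls_label]) + norm.logpdf(
            x, loc=mu, scale=np.sqrt(var)
        ).sum(axis=1)
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    return post[:, model.classes.index(model.positive)]


# ---------------------------------------------------------------------------
# stage 4: evaluation


@dataclass
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auc: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    scores: pd.Series = field(default_factory=pd.Series)  # posterior per sample

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_stats(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    """Sensitivity and specificity as percentages rounded to 2 decimals."""
    if min(tp, fp, tn, fn) < 0:
        raise DataError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise DataError("confusion table has an empty margin")
    sensitivity = round(100.0 * tp / (tp + fn), 2)
    specificity = round(100.0 * tn / (tn + fp), 2)
    return sensitivity, specificity


def roc_auc(
    scores: Sequence[float], labels: Sequence[str], positive: str = POSITIVE_CLASS
) -> tuple[float, pd.DataFrame]:
    """Trapezoidal AUC over all thresholds; equals the Mann-Whitney pair
    statistic with ties counted one half."""
    y = np.asarray([1 if l == positive else 0 for l in labels])
    if y.min() == y.max():
        raise DataError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return float(_trapezoid_auc(fpr, tpr)), pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _confusion(scores: np.ndarray, labels: pd.Series, positive: str, negative: str, threshold: float):
    predicted_pos = scores >= threshold
    actual_pos = (labels == positive).to_numpy()
    tp = int((predicted_pos & actual_pos).sum())
    fp = int((predicted_pos & ~actual_pos).sum())
    tn = int((~predicted_pos & ~actual_pos).sum())
    fn = int((~predicted_pos & actual_pos).sum())
    return tp, fp, tn, fn


def evaluate(
    model: NBModel,
    matrix: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.5,
) -> EvalResult:
    """Score a labelled cohort with a fitted model."""
    pos, neg = _two_groups(labels, model.positive)
    scores = nb_predict(model, matrix)
    tp, fp, tn, fn = _confusion(scores, labels, pos, neg, threshold)
    sens, spec = confusion_stats(tp, fp, tn, fn)
    auc_value, roc = roc_auc(scores, labels, pos)
    return EvalResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        auc=auc_value, roc=roc,
        scores=pd.Series(scores, index=labels.index, name="posterior"),
    )


def loocv(
    matrix: pd.DataFrame,
    labels: pd.Series,
    selection: Sequence[str] | None = None,
    threshold: float = 0.5,
    positive: str = POSITIVE_CLASS,
    nested: bool = False,
    alpha: float = 0.05,
    n_trees: int = 1000,
    k: int = 13,
    seed: int = 0,
) -> EvalResult:
    """Leave-one-out cross-validation of the naive-Bayes model.

    With ``selection`` given (the default workflow) the feature panel is
    fixed across folds; with ``nested=True`` the Welch filter and
    random-forest selection are re-run inside every fold, which removes
    selection leakage at the cost of n extra forest fits.
    """
    if len(labels) < 3:
        raise DataError("LOOCV needs at least 3 samples")
    pos, neg = _two_groups(labels, positive)
    if selection is None and not nested:
        raise ConfigurationError("provide a feature selection or set nested=True")
    scores = np.empty(len(labels))
    for i in range(len(labels)):
        train_idx = np.ones(len(labels), dtype=bool)
        train_idx[i] = False
        y_train = labels.iloc[train_idx]
        if y_train.nunique() < 2:
            raise DataError("a training fold lost one class entirely")
        x_train = matrix.iloc[train_idx]
        if nested:
            _, filtered = welch_filter(x_train, y_train, alpha=alpha, positive=pos)
            if not filtered:  # nothing survives the filter: fall back to the universe
                filtered = list(matrix.columns)
            fold_features = rf_importance_select(
                x_train, y_train, filtered, n_trees=n_trees, k=min(k, len(filtered)), seed=seed
            ).selected
        else:
            fold_features = tuple(selection)  # type: ignore[arg-type]
        model = nb_train(x_train[list(fold_features)], y_train, positive=pos)
        scores[i] = nb_predict(model, matrix.iloc[[i]][list(fold_features)])[0]
    tp, fp, tn, fn = _confusion(scores, labels, pos, neg, threshold)
    sens, spec = confusion_stats(tp, fp, tn, fn)
    auc_value, roc = roc_auc(scores, labels, pos)
    return EvalResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        auc=auc_value, roc=roc,
        scores=pd.Series(scores, index=labels.index, name="posterior"),
    )


def permutation_null_aucs(
    matrix: pd.DataFrame,
    labels: pd.Series,
    selection: Sequence[str],
    n_perm: int = 20,
    seed: int = 0,
    threshold: float = 0.5,
    positive: str = POSITIVE_CLASS,
) -> list[float]:
    """LOOCV AUC under label permutation with a fixed, a-priori feature panel.

    Because the panel is fixed before the labels are shuffled, each
    permuted AUC is an unbiased draw from the chance distribution.
    """
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_perm):
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        res = loocv(matrix, permuted, selection=selection, threshold=threshold, positive=positive)
        aucs.append(res.auc)
    return aucs


# ---------------------------------------------------------------------------
# unsupervised clustering of samples on the selected panel


def hcluster_features(
    matrix: pd.DataFrame,
    selected: Sequence[str] | None = None,
) -> tuple[list, np.ndarray]:
    """Average-linkage Euclidean clustering of samples on z-scored features.

    Returns the dendrogram leaf order (sample ids) and the 2-cluster cut
    labels (1/2 per sample).
    """
    if len(matrix) < 2:
        raise DataError("clustering needs >= 2 samples")
    x = matrix[list(selected)] if selected is not None else matrix
    std = x.std(axis=0, ddof=0)
    if (std == 0).all():
        warnings.warn("constant feature matrix: clustering is degenerate", stacklevel=2)
    z = (x - x.mean(axis=0)).div(std.replace(0.0, 1.0), axis=1).to_numpy(float)
    link = linkage(z, method="average", metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(link)]
    cut = fcluster(link, t=2, criterion="maxclust")
    return order, cut
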