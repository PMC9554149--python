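"""SVM classification of brain-metastasized vs other primary tumors.

A Gaussian-kernel support vector classifier with balanced class weights
separates the two sample classes; SVM-RFE (recursive feature elimination
on a linear-kernel SVM's weight vector, one feature dropped per round)
ranks enzyme genes by their contribution and selects the top k.
Performance is measured by stratified five-fold cross-validation with
out-of-fold decision scores pooled into one ROC curve.

Feature selection runs inside each training fold by default so the test
fold never informs the selection; a global pre-selection mode is available
for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class ClassifierSpec:
    """Settings of the Gaussian-kernel SVM.

    ``gamma="scale"`` sets the kernel width from the feature variance after
    standardization; features are standardized inside each training fold
    before the kernel is applied.
    """

    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str = "balanced"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVResult:
    """Pooled out-of-fold scores and the ROC they induce."""

    scores: pd.Series  # decision score per sample, out-of-fold
    fold_ids: pd.Series
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    selected_features: dict[int, list[str]] = field(default_factory=dict)


def make_svm(spec: ClassifierSpec) -> Pipeline:
    """Standardizer plus Gaussian-kernel SVC with balanced class weights."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel="rbf",
                    C=spec.C,
                    gamma=spec.gamma,
                    class_weight=spec.class_weight,
                    random_state=spec.seed,
                ),
            ),
        ]
    )


def _linear_svm(spec: ClassifierSpec) -> Pipeline:
    # RFE needs per-feature weights; the canonical SVM-RFE criterion is the
    # squared weight of a linear-kernel SVM.
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel="linear",
                    C=spec.C,
                    class_weight=spec.class_weight,
                    random_state=spec.seed,
                ),
            ),
        ]
    )


def stratified_kfold(labels: pd.Series, k: int = 5, seed: int = 0) -> pd.Series:
    """Assign each sample to one of k class-stratified folds."""
    counts = labels.value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"classes smaller than k={k}: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels.values)):
        fold[test_idx] = f
    return pd.Series(fold, index=labels.index, name="fold")


def roc_auc(scores: pd.Series, labels: pd.Series, positive_label=None) -> tuple[pd.DataFrame, float]:
    """ROC points and area under the curve.

    The trapezoidal area equals the Mann-Whitney probability that a
    positive sample outscores a negative one (ties counted half).
    """
    labels = labels.reindex(scores.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if positive_label is None:
        if all(isinstance(c, (int, np.integer, float)) for c in classes):
            positive_label = classes[-1]  # numeric labels: largest (1 in 0/1)
        elif "BMP" in classes:
            positive_label = "BMP"
        else:
            positive_label = classes[0]
    y = (labels == positive_label).astype(int)
    fpr, tpr, thresh = roc_curve(y, scores.values, drop_intermediate=False)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return roc, float(_trapezoid_auc(fpr, tpr))


def svm_rfe_rank(X: pd.DataFrame, y: pd.Series, spec: ClassifierSpec) -> pd.Series:
    """Full SVM-RFE ranking over features; rank 1 = most contributing.

    One feature is eliminated per round.  Constant features carry no
    class information; they are ranked with the rest but flagged with a
    warning.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    if y.reindex(X.index).nunique() < 2:
        raise ValueError("both classes must be present")
    const = X.columns[X.std(axis=0) == 0].tolist()
    if const:
        warnings.warn(f"constant features ranked without signal: {const}")
    # StandardScaler maps constant columns to 0, so the RFE below is
    # well-defined; scaling lives inside the eliminator via a pipeline-free
    # pre-transform because sklearn's RFE requires coef_ on the estimator.
    Xs = StandardScaler().fit_transform(X.values)
    svc = SVC(
        kernel="linear", C=spec.C, class_weight=spec.class_weight, random_state=spec.seed
    )
    rfe = RFE(svc, n_features_to_select=1, step=1)
    rfe.fit(Xs, y.reindex(X.index).values)
    return pd.Series(rfe.ranking_, index=X.columns, name="rank").sort_values(kind="stable")


def select_top_k(ranking: pd.Series, k: int = 20) -> list[str]:
    """The k best-ranked features."""
    if not 0 < k <= len(ranking):
        raise ValueError(f"k must be in [1, {len(ranking)}], got {k}")
    return ranking.sort_values(kind="stable").index[:k].tolist()


def run_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ClassifierSpec = ClassifierSpec(),
    k_folds: int = 5,
    positive_label: str = "BMP",
    select_k: int | None = None,
    select_within: list[str] | None = None,
    outside_cv: bool = False,
) -> CVResult:
    """Cross-validated SVM with pooled out-of-fold ROC.

    ``features`` is a samples x features table (e.g. the four physical
    features, the enzyme expressions, or their concatenation).  When
    ``select_k`` is given, SVM-RFE picks that many features — inside each
    training fold by default, or once on all samples when ``outside_cv``
    (leakage-prone, for comparison only).  ``select_within`` restricts the
    elimination to a column subset (e.g. the enzyme genes) while every
    other column is always kept, as in the combined physical + enzyme
    model.
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("every sample needs a label")
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ValueError(f"missing feature values in columns: {bad}")
    y = (labels == positive_label).astype(int)
    folds = stratified_kfold(labels, k=k_folds, seed=spec.seed)

    pool = features.columns if select_within is None else pd.Index(select_within)
    kept = features.columns.difference(pool, sort=False)

    def _select(X: pd.DataFrame, yy: pd.Series) -> pd.Index:
        ranking = svm_rfe_rank(X[pool], yy, spec)
        return kept.append(pd.Index(select_top_k(ranking, select_k)))

    global_selection: pd.Index | None = None
    if select_k is not None and outside_cv:
        global_selection = _select(features, y)

    scores = pd.Series(np.nan, index=features.index, dtype=float)
    selected: dict[int, list[str]] = {}
    for f in range(k_folds):
        train = folds != f
        test = folds == f
        cols = features.columns
        if global_selection is not None:
            cols = global_selection
        elif select_k is not None:
            cols = _select(features.loc[train], y.loc[train])
        selected[f] = list(cols)
        model = make_svm(spec)
        model.fit(features.loc[train, cols].values, y.loc[train].values)
        scores.loc[test] = model.decision_function(features.loc[test, cols].values)

    roc, auc_value = roc_auc(scores, y, positive_label=1)
    return CVResult(scores=scores, fold_ids=folds, roc=roc, auc=auc_value, selected_features=selected)
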