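"""LDA projection and SVM classification of per-particle feature vectors.

Two feature sets are compared throughout: the five polarization parameters
``[I, q, u, v, DOP]`` (``pol5``) and the same plus normalized fluorescence
``[I, q, u, v, DOP, F]`` (``pol5+F``).  The scientific question the
comparison answers is whether simultaneous fluorescence measurement improves
discrimination of populations whose polarization signatures overlap.

LDA finds the linear projection maximizing between-class over within-class
scatter (Fisher criterion); the projected coordinates x₁…x_k are the
low-dimensional parameters used for visualization.  The classifier is an
RBF-kernel SVM with a cross-validated grid search over the regularization
and kernel-width hyperparameters, evaluated on a stratified held-out split;
features are z-scored using training-split statistics only (intensity and
fluorescence live on very different scales from q, u, v).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "POL5", "POL6", "FEATURE_SETS",
    "ProjectionModel", "ClassifierReport",
    "lda_project", "svm_train_eval", "confusion_matrix",
]

POL5 = ["I", "q", "u", "v", "dop"]
POL6 = POL5 + ["F"]
FEATURE_SETS = {"pol5": POL5, "pol5+F": POL6}

DEFAULT_GRID = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.1, 1.0]}


@dataclass
class ProjectionModel:
    """Stored LDA transformation: x = (f − mean) · scalings."""

    feature_names: list
    scalings: np.ndarray        # (n_features, k)
    mean: np.ndarray            # (n_features,)
    class_means: pd.DataFrame   # class × projected coordinate

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy(dtype=float)
        return (x - self.mean) @ self.scalings


@dataclass
class ClassifierReport:
    """Held-out evaluation of one classifier run."""

    feature_set: str
    classes: list
    accuracy: float                     # overall held-out accuracy, fraction
    per_class_accuracy: dict            # class -> fraction
    confusion_counts: pd.DataFrame      # rows true, cols predicted
    confusion_percent: pd.DataFrame     # row-normalized, percent
    split: str
    hyperparameters: dict

    def __str__(self) -> str:  # human-readable summary for the CLI
        lines = [f"feature set: {self.feature_set}",
                 f"split: {self.split}",
                 f"hyperparameters: {self.hyperparameters}",
                 f"overall held-out accuracy: {self.accuracy:.1%}",
                 "per-class accuracy:"]
        lines += [f"  {c}: {a:.1%}" for c, a in self.per_class_accuracy.items()]
        lines.append("confusion matrix (row-normalized %):")
        lines.append(self.confusion_percent.round(1).to_string())
        return "\n".join(lines)


def lda_project(features: pd.DataFrame, labels, k: int,
                feature_names: list | None = None,
                ridge: float | None = None):
    """Fisher LDA projection of a feature table onto k discriminant axes.

    Returns (ProjectionModel, projected array).  ``ridge`` adds shrinkage to
    the within-class scatter when it is singular (e.g. a constant feature).
    """
    feature_names = feature_names or POL5
    y = np.asarray(labels)
    x = features[feature_names].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    if k > len(classes) - 1:
        raise ValueError(f"k must be <= n_classes - 1 = {len(classes) - 1}")
    if counts.min() < x.shape[1] + 1:
        raise ValueError("each class needs at least n_features + 1 records")
    lda = LinearDiscriminantAnalysis(
        solver="eigen", n_components=k,
        shrinkage=ridge if ridge is not None else None)
    try:
        projected = lda.fit_transform(x, y)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "within-class scatter is singular; pass ridge= to regularize "
            "(e.g. ridge=0.1 or 'auto')") from err
    scalings = lda.scalings_[:, :k]
    # the eigen solver projects without centering; keep the stored transform
    # identical to fit_transform by carrying a zero offset
    mean = np.zeros(x.shape[1])
    proj_means = pd.DataFrame(
        [np.asarray(m) @ scalings for m in lda.means_],
        index=classes, columns=[f"x{i + 1}" for i in range(k)])
    model = ProjectionModel(feature_names=list(feature_names),
                            scalings=scalings, mean=mean,
                            class_means=proj_means)
    return model, projected


def confusion_matrix(true, predicted) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw-count and row-normalized-percentage confusion matrices.

    Rows are true classes, columns predicted; each percentage row sums to
    100 (up to rounding).
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if len(true) != len(predicted):
        raise ValueError("true and predicted label vectors must have equal length")
    classes = sorted(set(true) | set(predicted))
    counts = _sk_confusion(true, predicted, labels=classes)
    counts_df = pd.DataFrame(counts, index=classes, columns=classes)
    row_sums = counts_df.sum(axis=1).replace(0, 1)
    percent_df = counts_df.div(row_sums, axis=0) * 100.0
    return counts_df, percent_df


def svm_train_eval(features: pd.DataFrame, labels,
                   feature_set: str = "pol5+F",
                   test_size: float = 0.30,
                   seed: int = 0,
                   grid: dict | None = None,
                   cv_folds: int = 5) -> ClassifierReport:
    """Train an RBF-kernel SVM with cross-validated hyperparameters and report
    held-out performance.

    A stratified ``test_size`` fraction is held out; the remainder feeds a
    ``cv_folds``-fold grid search over C and gamma.  Standardization is fit
    on the training split only.  Fully deterministic for a fixed seed and
    input ordering.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {sorted(FEATURE_SETS)}")
    cols = FEATURE_SETS[feature_set]
    x = features[cols].to_numpy(dtype=float)
    y = np.asarray(labels)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed)
    for split_name, split_y in (("train", y_tr), ("test", y_te)):
        missing = set(y) - set(split_y)
        if missing:
            raise ValueError(f"classes {sorted(missing)} absent from the {split_name} split")

    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    search = GridSearchCV(
        pipe, grid or DEFAULT_GRID,
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        n_jobs=1)
    search.fit(x_tr, y_tr)
    y_pred = search.predict(x_te)

    counts_df, percent_df = confusion_matrix(y_te, y_pred)
    per_class = {c: float(percent_df.loc[c, c]) / 100.0
                 for c in counts_df.index if counts_df.loc[c].sum() > 0}
    return ClassifierReport(
        feature_set=feature_set,
        classes=list(counts_df.index),
        accuracy=float(np.mean(y_pred == y_te)),
        per_class_accuracy=per_class,
        confusion_counts=counts_df,
        confusion_percent=percent_df,
        split=f"stratified {1 - test_size:.0%}/{test_size:.0%} (seed={seed})",
        hyperparameters={k.removeprefix("svc__"): v
                         for k, v in search.best_params_.items()},
    )
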