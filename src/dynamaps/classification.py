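"""Organellar classification of profiled proteins.

Compartment boundaries are learned from marker proteins with a
multi-class support vector machine (RBF kernel, one-vs-rest, class-
balanced).  Marker performance is assessed by stratified k-fold
cross-validation: pooled out-of-fold predictions give the global
prediction accuracy (fraction of markers assigned to their annotated
compartment) and per-cluster recall / precision / F1.  All proteins are
then scored against the trained boundaries; the winning class's
calibrated probability is the SVM score used to stratify predictions
into confidence classes, with marker accuracy inside each class serving
as a proxy for non-marker accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .io_formats import MarkerTable, _write_with_header
from .profiling import ProfileMatrix, marker_assignments

CONFIDENCE_CLASSES = ("high", "medium", "low", "very_low")

#: Hyperparameter grid for the nested cross-validation search.
DEFAULT_PARAM_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 1.0, 10.0]}


@dataclass
class ClusterMetrics:
    compartment: str
    recall: float
    precision: float
    f1: float
    n_markers: int


@dataclass
class ClassifierFit:
    """A trained organellar classifier plus its cross-validated marker metrics."""

    model: CalibratedClassifierCV
    classes: list[str]
    best_params: dict
    global_accuracy: float
    cluster_metrics: pd.DataFrame  # index compartment; recall/precision/f1/n_markers
    marker_cv: pd.DataFrame  # per marker: compartment, cv_prediction, cv_score, correct

    @property
    def confidence_cutoffs(self) -> tuple[float, float, float]:
        return calibrate_cutoffs(
            self.marker_cv["cv_score"].to_numpy(), self.marker_cv["correct"].to_numpy()
        )


def f1_score_from(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both vanish."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def train_and_crossvalidate(
    features: ProfileMatrix,
    markers: MarkerTable,
    folds: int = 5,
    seed: int = 0,
    param_grid: dict | None = None,
    small_class: str = "drop",
) -> ClassifierFit:
    """Fit the marker SVM and score it by stratified cross-validation.

    Hyperparameters are selected by an inner grid search on the marker
    set; pooled out-of-fold predicted probabilities (outer ``folds``-fold
    CV) give the reported metrics.  Compartments with fewer markers than
    ``folds`` are dropped with a warning (``small_class="drop"``) or the
    fold count is reduced to the smallest class (``"reduce_folds"``).
    """
    ann = marker_assignments(features, markers)
    is_marker = ann.notna()
    if is_marker.sum() == 0:
        raise ValueError("no marker protein matched the feature matrix")
    y = ann[is_marker]
    counts = y.value_counts()
    if (counts < folds).any():
        small = counts.index[counts < folds].tolist()
        if small_class == "drop":
            warnings.warn(f"dropping compartments with < {folds} markers: {small}")
            y = y[~y.isin(small)]
        elif small_class == "reduce_folds":
            folds = max(2, int(counts.min()))
            warnings.warn(f"reducing CV folds to {folds} for small compartments {small}")
        else:
            raise ValueError(f"compartments with < {folds} markers: {small}")
    if y.nunique() < 2:
        raise ValueError("training requires markers from at least two compartments")
    X = features.profiles.loc[y.index].to_numpy()

    grid = param_grid if param_grid is not None else DEFAULT_PARAM_GRID
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf", class_weight="balanced"), grid, cv=cv, scoring="accuracy"
    )
    search.fit(X, y)
    best = search.best_params_

    svc = CalibratedClassifierCV(
        SVC(kernel="rbf", class_weight="balanced", random_state=seed, **best),
        method="sigmoid",
        cv=3,
        ensemble=False,
    )
    proba = cross_val_predict(svc, X, y, cv=cv, method="predict_proba")
    classes = sorted(y.unique())
    cv_pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    cv_score = proba.max(axis=1)
    correct = cv_pred == y.to_numpy()
    global_accuracy = float(np.mean(correct))

    prec, rec, f1, support = precision_recall_fscore_support(
        y, cv_pred, labels=classes, zero_division=0
    )
    metrics = pd.DataFrame(
        {"recall": rec, "precision": prec, "f1": f1, "n_markers": support},
        index=pd.Index(classes, name="compartment"),
    )
    marker_cv = pd.DataFrame(
        {
            "compartment": y,
            "cv_prediction": cv_pred,
            "cv_score": cv_score,
            "correct": correct,
        },
        index=y.index,
    )
    model = svc.fit(X, y)
    return ClassifierFit(model, classes, best, global_accuracy, metrics, marker_cv)


def predict_all(
    model: CalibratedClassifierCV, features: ProfileMatrix, markers: MarkerTable | None = None
) -> pd.DataFrame:
    """Score every profiled protein against the trained boundaries.

    Returns one row per protein: ``predicted_compartment`` (argmax of the
    calibrated class probabilities; exact ties resolve to the
    alphabetically first class and are flagged), ``svm_score`` (the
    winning probability), and marker annotation columns.
    """
    X = features.profiles.to_numpy()
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} != model's {model.n_features_in_}"
        )
    proba = model.predict_proba(X)
    classes = np.asarray(model.classes_)  # sklearn stores these sorted
    winner = np.argmax(proba, axis=1)
    top = proba[np.arange(len(proba)), winner]
    tie = (np.isclose(proba, top[:, None], rtol=0.0, atol=1e-12).sum(axis=1)) > 1
    out = pd.DataFrame(
        {
            "predicted_compartment": classes[winner],
            "svm_score": top,
            "tie": tie,
        },
        index=features.protein_ids,
    )
    if markers is not None:
        ann = marker_assignments(features, markers)
        out["is_marker"] = ann.notna()
        out["marker_compartment"] = ann
    else:
        out["is_marker"] = False
        out["marker_compartment"] = np.nan
    return out


def calibrate_cutoffs(
    scores: np.ndarray,
    correct: np.ndarray,
    targets: tuple[float, float, float] = (0.95, 0.90, 0.80),
) -> tuple[float, float, float]:
    """SVM-score cutoffs giving at least the target marker accuracy above each.

    For each target accuracy, the smallest observed score s is chosen such
    that markers scoring >= s are predicted with at least that accuracy;
    cutoffs are forced strictly descending.
    """
    order = np.argsort(scores)[::-1]
    s_sorted = scores[order]
    acc = np.cumsum(correct[order]) / np.arange(1, len(order) + 1)
    cutoffs = []
    prev = np.inf
    for t in sorted(targets, reverse=True):
        ok = np.nonzero(acc >= t)[0]
        cut = s_sorted[ok[-1]] if len(ok) else s_sorted[0]
        cut = min(cut, prev - 1e-12)
        cutoffs.append(float(cut))
        prev = cut
    return tuple(cutoffs)  # type: ignore[return-value]


def assign_confidence(
    results: pd.DataFrame, cutoffs: tuple[float, float, float]
) -> pd.Series:
    c1, c2, c3 = cutoffs
    if not (c1 > c2 > c3):
        raise ValueError(f"cutoffs must be strictly descending, got {cutoffs}")
    s = results["svm_score"].to_numpy()
    cls = np.select([s >= c1, s >= c2, s >= c3], CONFIDENCE_CLASSES[:3], CONFIDENCE_CLASSES[3])
    return pd.Series(cls, index=results.index, name="confidence_class")


def stratify_confidence(
    results: pd.DataFrame, cutoffs: tuple[float, float, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition predictions into confidence classes and summarize each.

    Returns the results table with a ``confidence_class`` column and a
    per-class summary: marker accuracy (NaN when a class holds no
    markers, never 0), non-marker count and non-marker proportion.
    """
    res = results.copy()
    res["confidence_class"] = assign_confidence(res, cutoffs)
    total_nonmarker = int((~res["is_marker"]).sum())
    rows = []
    for cls in CONFIDENCE_CLASSES:
        sub = res[res["confidence_class"] == cls]
        mk = sub[sub["is_marker"]]
        acc = (
            float((mk["predicted_compartment"] == mk["marker_compartment"]).mean())
            if len(mk)
            else np.nan
        )
        n_non = int((~sub["is_marker"]).sum())
        rows.append(
            {
                "confidence_class": cls,
                "n_markers": len(mk),
                "marker_accuracy": acc,
                "n_nonmarker": n_non,
                "proportion_nonmarker": n_non / total_nonmarker if total_nonmarker else np.nan,
            }
        )
    return res, pd.DataFrame(rows).set_index("confidence_class")


def concordance(
    a: pd.DataFrame, b: pd.DataFrame, min_score: float = -np.inf
) -> tuple[int, float]:
    """Agreement between two maps' non-marker predictions.

    Restricted to non-marker proteins present in both results with
    ``svm_score >= min_score`` in both; returns the number compared and
    the fraction with identical predicted compartments (NaN when no
    protein qualifies).
    """
    shared = a.index.intersection(b.index)
    aa, bb = a.loc[shared], b.loc[shared]
    keep = (
        ~aa["is_marker"].astype(bool)
        & ~bb["is_marker"].astype(bool)
        & (aa["svm_score"] >= min_score)
        & (bb["svm_score"] >= min_score)
    )
    n = int(keep.sum())
    if n == 0:
        return 0, float("nan")
    frac = float(
        (aa.loc[keep, "predicted_compartment"] == bb.loc[keep, "predicted_compartment"]).mean()
    )
    return n, frac


def pca_projection(
    features: ProfileMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centered PCA scores of the profile feature matrix.

    A deterministic sign convention is applied per component: the loading
    of largest magnitude is made positive.  Returns the score table
    (columns ``PC1..PCk``) and the explained-variance ratios.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = features.profiles.to_numpy()
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the feature dimension")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
            pca.components_[j] *= -1.0
    df = pd.DataFrame(
        scores,
        index=features.protein_ids,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return df, pca.explained_variance_ratio_


def write_classification(results: pd.DataFrame, path, params: dict | None = None) -> None:
    out = results.reset_index().rename(
        columns={
            "protein_id": "Protein ID",
            "predicted_compartment": "Predicted compartment",
            "svm_score": "SVM score",
            "confidence_class": "Confidence class",
            "marker_compartment": "Marker compartment",
        }
    )
    _write_with_header(out, path, params)
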