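"""Footwear recognition (sport shoes vs high heels) from loading-response GRF.

The loading response is where heel geometry changes the force signal most,
so the classifier sees, per stride, the least-squares coefficients of a
5th-degree polynomial fitted to each of the vertical and anterior-posterior
components of both limbs over the LR window: 4 curves x 6 coefficients = a
24-element input vector.  Time is rescaled to [0, 1] before fitting so the
coefficients are comparable across stride durations, and forces are in
fraction of body weight so the features are weight-invariant.

Cross-validation is grouped by subject: strides of one person never span a
training and a test fold, which prevents identity leakage into the footwear
decision.  High heels are the positive class.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .phases import phase_window
from .types import HEELS, StrideRecord

POLY_DEGREE = 5
N_FEATURES = 24
#: Fitting order: component (anterior-posterior, vertical) x limb (L, R),
#: coefficients listed by descending degree within each block.
FEATURE_BLOCKS = (("fx", "L"), ("fx", "R"), ("fy", "L"), ("fy", "R"))


def lr_poly_features(stride: StrideRecord) -> np.ndarray:
    """24 polynomial coefficients of the loading-response curves.

    Raises ``ValueError`` when the LR window holds fewer than 6 samples
    (the degree-5 fit would be underdetermined).
    """
    window = phase_window(stride.n_samples, "LR")
    if len(window) < POLY_DEGREE + 1:
        raise ValueError(
            f"LR window has {len(window)} samples; need at least {POLY_DEGREE + 1}"
        )
    t = np.linspace(0.0, 1.0, len(window))
    coeffs = np.empty(N_FEATURES, dtype=np.float64)
    for i, (comp, limb) in enumerate(FEATURE_BLOCKS):
        f = stride.column(limb, comp)[window.start_index : window.end_index]
        f = f / stride.body_weight_n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coeffs[i * 6 : (i + 1) * 6] = np.polyfit(t, f, POLY_DEGREE)
    return coeffs


def footwear_dataset(
    strides: Sequence[StrideRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix, labels (1 = heels) and subject groups for a batch."""
    X = np.vstack([lr_poly_features(s) for s in strides])
    y = np.array([1 if s.footwear == HEELS else 0 for s in strides], dtype=np.int64)
    groups = np.array([s.subject_id for s in strides])
    return X, y, groups


def train_footwear(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    model: str = "svm",
    svm_c: float = 10.0,
    knn_neighbors: int = 3,
):
    """Fit the footwear classifier.

    Default model: soft-margin SVM with an RBF kernel on standardized
    features.  A k-nearest-neighbor alternative (city-block metric) is
    selectable for comparison.  Training rows are sorted canonically before
    fitting, so predictions are invariant to training-row order, and the
    fit is deterministic given the seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both footwear classes")
    order = np.lexsort(np.vstack([X.T, y]))
    X, y = X[order], y[order]
    if model == "svm":
        clf = SVC(C=svm_c, kernel="rbf", gamma="scale", random_state=int(seed))
    elif model == "knn":
        clf = KNeighborsClassifier(n_neighbors=knn_neighbors, metric="manhattan")
    else:
        raise ValueError(f"unknown model {model!r}; expected 'svm' or 'knn'")
    pipeline = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    pipeline.fit(X, y)
    return pipeline


def predict_footwear(classifier, X: np.ndarray) -> np.ndarray:
    """Hard footwear labels (0 = sport, 1 = heels) for feature rows."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return classifier.predict(X).astype(np.int64)


def grouped_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    model: str = "svm",
) -> dict:
    """Subject-grouped k-fold cross-validation of the footwear classifier.

    Folds partition subjects, not strides.  Returns per-fold CCR,
    sensitivity and specificity (heels positive) in percent, plus their
    means and standard deviations.
    """
    groups = np.asarray(groups)
    unique_groups = np.unique(groups)
    if unique_groups.size < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct subjects, got {unique_groups.size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 503]))
    shuffled = rng.permutation(unique_groups)
    fold_rows = []
    for fold_groups in np.array_split(shuffled, n_folds):
        test_mask = np.isin(groups, fold_groups)
        clf = train_footwear(X[~test_mask], y[~test_mask], seed=seed, model=model)
        pred = predict_footwear(clf, X[test_mask])
        truth = y[test_mask]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        fold_rows.append(
            {
                "ccr": 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1),
                "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
                "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    folds = pd.DataFrame(fold_rows)
    result = {"folds": folds}
    for metric in ("ccr", "sensitivity", "specificity"):
        result[f"{metric}_mean"] = float(folds[metric].mean())
        result[f"{metric}_sd"] = float(folds[metric].std(ddof=1))
    return result


def save_classifier(classifier, path) -> None:
    joblib.dump({"format": 1, "classifier": classifier}, path)


def load_classifier(path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != 1:
        raise ValueError(f"unrecognized classifier file: {path}")
    return payload["classifier"]
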