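"""Dimensionality reduction and tissue classification.

PCA is computed from the eigendecomposition of the column-mean-centered
covariance matrix, components ordered by decreasing eigenvalue, with a fixed
sign convention (largest-magnitude loading entry positive) so results are
reproducible.  Classification uses a soft-margin SVM with an RBF kernel
(one-vs-one multiclass).  Evaluation produces a 3x3 confusion matrix over
(normal, edge, center) and binary metrics after collapsing edge and center
into a single "malignant" positive class:

    accuracy    = (TP + TN) / N
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .spectra_io import TISSUE_CLASSES

MALIGNANT = ("edge", "center")


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray      # (n_components_total, n_features), orthonormal rows
    eigenvalues: np.ndarray   # non-increasing, non-negative
    n_components: int = 2

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def fit_pca(X: np.ndarray, n_components: int = 2) -> PCAModel:
    """Eigendecomposition of the covariance matrix of column-centered data."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ClassifyError("need a 2-D matrix with >= 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    n, p = Xc.shape
    # eigh on the smaller Gram side keeps wide spectral matrices cheap
    if p <= n:
        cov = Xc.T @ Xc / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        loadings = evecs[:, order].T
    else:
        gram = Xc @ Xc.T / (n - 1)
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        nonzero = evals > 1e-12 * max(evals.max(), 1.0)
        loadings = np.zeros((evals.size, p))
        loadings[nonzero] = (Xc.T @ evecs[:, nonzero]
                             / np.sqrt((n - 1) * evals[nonzero])).T
    evals = np.maximum(evals, 0.0)
    if np.allclose(evals, 0.0):
        import warnings
        warnings.warn("constant matrix: all eigenvalues zero", stacklevel=2)
    # sign convention: largest-|.| entry of each loading is positive
    for i in range(loadings.shape[0]):
        row = loadings[i]
        if row.any() and row[np.argmax(np.abs(row))] < 0:
            loadings[i] = -row
    return PCAModel(mean=mean, loadings=loadings, eigenvalues=evals,
                    n_components=min(n_components, loadings.shape[0]))


def project(model: PCAModel, X: np.ndarray,
            n_components: int | None = None) -> np.ndarray:
    """Project rows of X onto the leading principal components."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean.size:
        raise ClassifyError(
            f"feature count {X.shape[-1]} != model dimension {model.mean.size}")
    k = n_components if n_components is not None else model.n_components
    return (X - model.mean) @ model.loadings[:k].T


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.30
    min_per_class: int = 5
    group_by_patient: bool = False
    seed: int = 0


def _train_count(class_size: int, plan: SplitPlan) -> int:
    # half-up rounding: 30% of 15 must give 5, not banker's 4
    return max(int(np.floor(plan.train_fraction * class_size + 0.5)),
               plan.min_per_class)


def split_train_test(labels: Sequence[str], plan: SplitPlan,
                     patients: Sequence[str] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split with a per-class training minimum.

    Per class, training count = max(round(fraction x size), min_per_class).
    With ``group_by_patient`` all spectra of one patient land on one side.
    Returns (train_indices, test_indices), disjoint and exhaustive.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(plan.seed)
    classes = [c for c in TISSUE_CLASSES if c in set(labels)]
    for cls in classes:
        size = int(np.sum(labels == cls))
        if _train_count(size, plan) >= size:
            raise ClassifyError(
                f"class {cls!r} (n={size}) cannot supply "
                f"{_train_count(size, plan)} training rows and a non-empty test set")

    if not plan.group_by_patient:
        train: list[int] = []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            n_train = _train_count(idx.size, plan)
            train.extend(rng.choice(idx, size=n_train, replace=False))
        train_idx = np.sort(np.array(train, dtype=int))
        test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
        return train_idx, test_idx

    if patients is None:
        raise ClassifyError("group_by_patient requires per-row patient ids")
    patients = np.asarray(patients, dtype=object)
    for cls in classes:
        if len(set(patients[labels == cls])) < 2:
            raise ClassifyError(
                f"class {cls!r} comes from a single patient; a grouped split "
                f"cannot place it in both train and test")
    uniq = sorted(set(patients))
    order = rng.permutation(len(uniq))
    counts = {cls: 0 for cls in classes}
    targets = {cls: _train_count(int(np.sum(labels == cls)), plan)
               for cls in classes}
    train_patients: set = set()
    for j in order:
        if all(counts[c] >= targets[c] for c in classes):
            break
        pat = uniq[j]
        rows = patients == pat
        # skip a patient whose inclusion would empty some class's test side
        ok = True
        for cls in classes:
            cls_rows = labels == cls
            if np.sum(cls_rows & ~rows & ~np.isin(
                    patients, list(train_patients))) < 1 and np.any(cls_rows & rows):
                ok = False
        if not ok:
            continue
        if any(np.any((labels == c) & rows) and counts[c] < targets[c]
               for c in classes):
            train_patients.add(pat)
            for cls in classes:
                counts[cls] += int(np.sum((labels == cls) & rows))
    if any(counts[c] < targets[c] for c in classes):
        short = [c for c in classes if counts[c] < targets[c]]
        raise ClassifyError(
            f"grouped split cannot reach the training minimum for {short}")
    train_idx = np.flatnonzero(np.isin(patients, list(train_patients)))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    if test_idx.size == 0:
        raise ClassifyError("grouped split left an empty test set")
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RBFSVMConfig:
    C: float = 1.0
    gamma: float | str = "scale"   # 1 / (n_features * feature variance)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ClassifyError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ClassifyError("gamma must be positive")


def train_svm(X: np.ndarray, labels: Sequence[str],
              cfg: RBFSVMConfig | None = None) -> SVC:
    """Soft-margin RBF-kernel SVM, one-vs-one multiclass, deterministic."""
    cfg = cfg or RBFSVMConfig()
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise ClassifyError("training set contains a single class")
    clf = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma,
              decision_function_shape="ovo", random_state=0)
    clf.fit(np.asarray(X, dtype=float), labels.astype(str))
    return clf


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    confusion: np.ndarray         # 3x3, rows=true, cols=pred, normal/edge/center
    class_order: tuple[str, ...]
    accuracy: float
    sensitivity: float
    specificity: float
    variant: str = ""
    split_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "split_seed": self.split_seed,
        }


def binary_metrics_from_confusion(conf: np.ndarray,
                                  class_order: Sequence[str] = TISSUE_CLASSES
                                  ) -> tuple[float, float, float]:
    """Collapse a 3x3 confusion matrix to malignant-vs-normal metrics.

    Positive = predicted (or true) edge or center; any malignant-subtype
    prediction counts as positive regardless of edge/center confusion.
    """
    conf = np.asarray(conf)
    pos = [i for i, c in enumerate(class_order) if c in MALIGNANT]
    neg = [i for i, c in enumerate(class_order) if c not in MALIGNANT]
    tp = conf[np.ix_(pos, pos)].sum()
    fn = conf[np.ix_(pos, neg)].sum()
    tn = conf[np.ix_(neg, neg)].sum()
    fp = conf[np.ix_(neg, pos)].sum()
    n = tp + fn + tn + fp
    accuracy = (tp + tn) / n if n else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(accuracy), float(sensitivity), float(specificity)


def evaluate(classifier: SVC, X_test: np.ndarray,
             labels_test: Sequence[str], variant: str = "",
             split_seed: int | None = None) -> ClassificationReport:
    """Predict the test rows and assemble the report."""
    labels_test = np.asarray(labels_test, dtype=object)
    if labels_test.size == 0:
        raise ClassifyError("test set is empty")
    unknown = set(labels_test) - set(TISSUE_CLASSES)
    if unknown:
        raise ClassifyError(f"unseen labels in test set: {sorted(unknown)}")
    pred = classifier.predict(np.asarray(X_test, dtype=float))
    conf = confusion_matrix(labels_test.astype(str), pred,
                            labels=list(TISSUE_CLASSES))
    acc, sens, spec = binary_metrics_from_confusion(conf)
    return ClassificationReport(
        confusion=conf, class_order=TISSUE_CLASSES, accuracy=acc,
        sensitivity=sens, specificity=spec, variant=variant,
        split_seed=split_seed)


@dataclass
class RepeatedSummary:
    variant: str
    reports: list[ClassificationReport]

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.reports])

    def mean(self, attr: str) -> float:
        return float(np.nanmean(self._vals(attr)))

    def sd(self, attr: str) -> float:
        return float(np.nanstd(self._vals(attr), ddof=1)) if len(self.reports) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_repeats": len(self.reports),
            **{f"{m}_mean": self.mean(m)
               for m in ("accuracy", "sensitivity", "specificity")},
            **{f"{m}_sd": self.sd(m)
               for m in ("accuracy", "sensitivity", "specificity")},
            "per_repeat": [r.to_dict() for r in self.reports],
        }
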