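"""Multiclass classification of VOI descriptors and method comparison.

The classifier is a soft-margin SVM extended to q classes by the
one-against-one scheme: one binary SVM per class pair (q(q-1)/2 machines),
predictions by majority vote, ties broken by the fixed class-vocabulary
order (CON, GGO, HCM, EMP, NOD, NOR).  The binary machines are LIBSVM via
scikit-learn's SVC; the voting wrapper lives here so the tie rule is exact.

Two kernels are supported: the linear kernel K(x, y) = x^T y used with
average-pooled sparse descriptors, and the exponential chi-squared kernel
H(x, y) = exp(-alpha * sum_t (x_t - y_t)^2 / (x_t + y_t)) used with
bag-of-words histograms (terms with x_t + y_t = 0 contribute 0).

Also here: evaluation reports (confusion matrix, overall accuracy, one-vs-
rest sensitivity/specificity) and McNemar's paired test between two
classifiers' predictions on a common test set (exact two-sided binomial on
the discordant counts, plus the continuity-corrected chi-square version).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .pooling import Descriptor
from .volume import PATTERN_LABELS


def _as_matrix(descriptors) -> np.ndarray:
    if isinstance(descriptors, np.ndarray):
        X = descriptors
    else:
        X = np.stack(
            [d.values if isinstance(d, Descriptor) else np.asarray(d, dtype=float)
             for d in descriptors]
        )
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("descriptors must form a 2D matrix")
    if not np.isfinite(X).all():
        raise ValueError("descriptor matrix contains NaN or infinite entries")
    return X


def linear_kernel(x_i, x_j) -> float:
    """Plain inner product of two descriptors."""
    a = np.asarray(x_i, dtype=float).ravel()
    b = np.asarray(x_j, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"descriptor lengths differ: {a.shape[0]} vs {b.shape[0]}")
    return float(a @ b)


def chi2_kernel(x_i, x_j, alpha: float = 1.0) -> float:
    """Exponential chi-squared kernel between two nonnegative histograms."""
    a = np.asarray(x_i, dtype=float).ravel()
    b = np.asarray(x_j, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"histogram lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("chi-squared kernel requires nonnegative histograms")
    s = a + b
    d = a - b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, d * d / np.where(s > 0, s, 1.0), 0.0)
    return float(np.exp(-alpha * terms.sum()))


def _chi2_gram(A: np.ndarray, B: np.ndarray, alpha: float) -> np.ndarray:
    """Pairwise chi-squared kernel matrix between rows of A and rows of B."""
    a = A[:, None, :]
    b = B[None, :, :]
    s = a + b
    d = a - b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, d * d / np.where(s > 0, s, 1.0), 0.0)
    return np.exp(-alpha * terms.sum(axis=2))


def _class_order(labels) -> list[str]:
    present = set(labels)
    ordered = [c for c in PATTERN_LABELS if c in present]
    ordered += sorted(present - set(PATTERN_LABELS))
    return ordered


@dataclass
class ClassifierModel:
    """One-against-one multiclass SVM over VOI descriptors."""

    kernel: str
    C: float
    alpha: float
    classes: list[str]
    machines: dict[tuple[int, int], SVC] = field(default_factory=dict)
    # training descriptors per pair are needed to evaluate the precomputed
    # chi-squared kernel at prediction time
    pair_X: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    n_features: int = 0

    @property
    def n_machines(self) -> int:
        return len(self.machines)


def train_classifier(
    descriptors, labels, kernel: str = "linear", C: float = 1.0, alpha: float = 1.0
) -> ClassifierModel:
    """Fit the one-against-one SVM on labeled descriptors.

    ``kernel`` is ``"linear"`` or ``"chi2"``; ``alpha`` only matters for the
    chi-squared kernel.  Deterministic given its inputs.
    """
    X = _as_matrix(descriptors)
    y = np.asarray(list(labels))
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} descriptors but {y.shape[0]} labels")
    classes = _class_order(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")
    if kernel not in ("linear", "chi2"):
        raise ValueError(f"unknown kernel {kernel!r}; expected 'linear' or 'chi2'")
    model = ClassifierModel(
        kernel=kernel, C=C, alpha=alpha, classes=classes, n_features=X.shape[1]
    )
    for i, j in combinations(range(len(classes)), 2):
        mask = (y == classes[i]) | (y == classes[j])
        Xp, yp = X[mask], (y[mask] == classes[j]).astype(int)  # 1 means class j
        if kernel == "linear":
            svc = SVC(kernel="linear", C=C)
            svc.fit(Xp, yp)
        else:
            svc = SVC(kernel="precomputed", C=C)
            svc.fit(_chi2_gram(Xp, Xp, alpha), yp)
            model.pair_X[(i, j)] = Xp
        model.machines[(i, j)] = svc
    return model


def predict(model: ClassifierModel, descriptors) -> list[str]:
    """Predict labels by one-against-one voting.

    Vote ties go to the class earliest in the vocabulary order (the order of
    ``model.classes``), which np.argmax implements directly.
    """
    if isinstance(descriptors, (list, tuple)) and len(descriptors) == 0:
        return []
    X = _as_matrix(descriptors)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"descriptors have {X.shape[1]} features, model expects {model.n_features}"
        )
    votes = np.zeros((X.shape[0], len(model.classes)), dtype=int)
    for (i, j), svc in model.machines.items():
        if model.kernel == "linear":
            pred = svc.predict(X)
        else:
            pred = svc.predict(_chi2_gram(X, model.pair_X[(i, j)], model.alpha))
        votes[:, j] += pred
        votes[:, i] += 1 - pred
    winners = np.argmax(votes, axis=1)  # ties -> lowest index = vocab order
    return [model.classes[w] for w in winners]


@dataclass
class EvaluationReport:
    """Confusion matrix and summary metrics for one method on one test set."""

    confusion: pd.DataFrame  # rows true, columns predicted
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    predictions: list[str]
    truth: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Per-class sensitivity/specificity as a tidy table."""
        return pd.DataFrame(
            {
                "sensitivity": pd.Series(self.sensitivity),
                "specificity": pd.Series(self.specificity),
            }
        )


def evaluate(predictions, truth, classes=None) -> EvaluationReport:
    """Confusion matrix, overall accuracy and one-vs-rest per-class rates."""
    preds = list(predictions)
    true = list(truth)
    if len(preds) != len(true):
        raise ValueError(f"{len(preds)} predictions but {len(true)} truths")
    if classes is None:
        classes = _class_order(set(true) | set(preds))
    idx = {c: i for i, c in enumerate(classes)}
    q = len(classes)
    cm = np.zeros((q, q), dtype=int)
    for t, p in zip(true, preds):
        cm[idx[t], idx[p]] += 1
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    sensitivity, specificity = {}, {}
    for c, i in idx.items():
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sensitivity[c] = float(tp / (tp + fn)) if tp + fn else float("nan")
        specificity[c] = float(tn / (tn + fp)) if tn + fp else float("nan")
    confusion = pd.DataFrame(cm, index=list(classes), columns=list(classes))
    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        predictions=preds,
        truth=true,
    )


@dataclass
class McNemarResult:
    """Discordance table and p-values of McNemar's paired test."""

    b: int  # a correct, b wrong
    c: int  # a wrong, b correct
    p_exact: float
    chi2_statistic: float
    p_chi2: float

    @property
    def p_value(self) -> float:
        """The primary (exact binomial) p-value."""
        return self.p_exact


def mcnemar_test(pred_a, pred_b, truth) -> McNemarResult:
    """McNemar's test between two prediction vectors on a common test set.

    The 2x2 discordance table counts items method A got right and B wrong
    (b) and vice versa (c).  The primary p-value is the exact two-sided
    binomial test of b successes in b+c trials at rate 1/2, valid at any
    discordance count; the continuity-corrected chi-square approximation
    (|b-c| - 1)^2 / (b+c) on 1 df is also reported.
    """
    a = np.asarray(list(pred_a))
    b_ = np.asarray(list(pred_b))
    t = np.asarray(list(truth))
    if not (a.shape == b_.shape == t.shape):
        raise ValueError("prediction and truth vectors must have equal length")
    a_ok = a == t
    b_ok = b_ == t
    b_count = int(np.sum(a_ok & ~b_ok))
    c_count = int(np.sum(~a_ok & b_ok))
    n = b_count + c_count
    if n == 0:
        return McNemarResult(0, 0, 1.0, 0.0, 1.0)
    p_exact = float(stats.binomtest(b_count, n, 0.5).pvalue)
    chi2 = (abs(b_count - c_count) - 1) ** 2 / n
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(b_count, c_count, p_exact, float(chi2), p_chi2)


__all__ = [
    "ClassifierModel",
    "EvaluationReport",
    "McNemarResult",
    "chi2_kernel",
    "evaluate",
    "linear_kernel",
    "mcnemar_test",
    "predict",
    "train_classifier",
]
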