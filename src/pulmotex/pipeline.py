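"""End-to-end orchestration of the four method variants.

Each variant shares the same skeleton — local features, overcomplete
dictionary, per-feature coding, spatial pooling, SVM — and differs only in
the dictionary learner, the coder and the kernel:

=======  ==========  ===========  =========  ========
method   dictionary  coder        pooling    kernel
=======  ==========  ===========  =========  ========
SR1      K-SVD       OMP          average    linear
SR2      K-Means     OMP          average    linear
SR3      K-Means     OMP1         average    linear
BOW      K-Means     hard assign  histogram  chi2
=======  ==========  ===========  =========  ========

Feature vectors are z-scored per dimension with training-set statistics
before dictionary learning and coding (the 16 dimensions mix attenuation
means with dimensionless kurtoses, so raw scales are incomparable); the
transform is stored with the trained method and applied to test VOIs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from . import classify
from .coding import batch_hard_assign, batch_omp, batch_omp1
from .dictionary import Dictionary, kmeans_dictionary, ksvd
from .features import extract_features
from .pooling import pool_coefficients
from .volume import VOI_SHAPE, LabeledDataset

logger = logging.getLogger(__name__)

METHODS = ("SR1", "SR2", "SR3", "BOW")

#: method -> (dictionary learner, coder, pooling, kernel)
METHOD_TABLE = {
    "SR1": ("ksvd", "omp", "average", "linear"),
    "SR2": ("kmeans", "omp", "average", "linear"),
    "SR3": ("kmeans", "omp1", "average", "linear"),
    "BOW": ("kmeans", "hard", "bow_histogram", "chi2"),
}

#: Parameter grids used for cross-validated model selection: patch edge
#: 2..6, atoms 500..3000 step 500, sparsity 2..14 step 2, C = 2^-2..2^12;
#: bag-of-words uses 50..400 words step 50 and alpha = 2^-10..2^1.
FULL_GRIDS = {
    "SR": dict(
        patch_size=list(range(2, 7)),
        k_atoms=list(range(500, 3001, 500)),
        T=list(range(2, 15, 2)),
        C=[2.0**p for p in range(-2, 13)],
    ),
    "BOW": dict(
        patch_size=list(range(2, 7)),
        k_atoms=list(range(50, 401, 50)),
        T=[1],
        C=[2.0**p for p in range(-2, 13)],
        alpha=[2.0**p for p in range(-10, 2)],
    ),
}

#: Desk-scale grids for quick experiments and the CLI's ``--grid reduced``.
REDUCED_GRIDS = {
    "SR": dict(patch_size=[3, 4], k_atoms=[64, 128], T=[2, 4], C=[1.0, 16.0]),
    "BOW": dict(patch_size=[3], k_atoms=[32, 64], T=[1], C=[1.0, 16.0], alpha=[0.5, 1.0]),
}


@dataclass
class MethodConfig:
    """Hyperparameters of one method variant."""

    method: str
    patch_size: int = 3
    step: int = 4
    k_atoms: int = 256
    T: int = 2
    C: float = 1.0
    alpha: float = 1.0  # chi-squared kernel width, BOW only
    standardize_features: bool = True
    dict_seed: int = 0
    dict_max_iter: int | None = None  # None -> learner default

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (2 <= self.patch_size <= 6):
            raise ValueError(f"patch_size must be in 2..6, got {self.patch_size}")
        if self.method == "BOW" and self.T != 1:
            logger.warning(
                "BOW is sparsity-1 by definition; ignoring configured T=%d", self.T
            )
            self.T = 1

    @property
    def components(self) -> tuple[str, str, str, str]:
        return METHOD_TABLE[self.method]


@dataclass
class TrainedMethod:
    """Everything needed to classify new VOIs with one trained variant."""

    config: MethodConfig
    dictionary: Dictionary
    scaler: StandardScaler | None
    classifier: classify.ClassifierModel
    training_log: dict = field(default_factory=dict)


class FeatureCache:
    """Memo of stacked dataset features keyed by (dataset, patch_size, step).

    Local features depend only on the voxel data and the patch geometry —
    not on k/T/C or the method — so one extraction can serve every method
    variant and every grid point sharing a patch size.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def get(self, dataset: LabeledDataset, patch_size: int, step: int):
        key = (id(dataset), patch_size, step)
        if key not in self._store:
            self._store[key] = _extract_dataset_features(dataset, patch_size, step)
        return self._store[key]


def _extract_dataset_features(
    dataset: LabeledDataset, patch_size: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked local features of all VOIs plus per-row VOI indices."""
    blocks, owners = [], []
    for i, vol in enumerate(dataset.volumes):
        fm = extract_features(vol, patch_size, step, expected_shape=VOI_SHAPE)
        blocks.append(fm.rows)
        owners.append(np.full(fm.n_rows, i))
    return np.vstack(blocks), np.concatenate(owners)


def _dataset_features(
    dataset: LabeledDataset, patch_size: int, step: int, cache: "FeatureCache | None" = None
) -> tuple[np.ndarray, np.ndarray]:
    if cache is not None:
        return cache.get(dataset, patch_size, step)
    return _extract_dataset_features(dataset, patch_size, step)


def _encode_and_pool(
    atoms: np.ndarray, X: np.ndarray, owners: np.ndarray, n_vois: int,
    coder: str, pooling: str, T: int,
) -> np.ndarray:
    """Descriptor matrix (n_vois, k): code all rows, pool per VOI."""
    if coder == "omp":
        supports, coefs, n_sel, _ = batch_omp(atoms, X, T)
    elif coder == "omp1":
        supports, coefs, n_sel, _ = batch_omp1(atoms, X, T)
    elif coder == "hard":
        supports, coefs, n_sel, _ = batch_hard_assign(atoms, X)
    else:  # pragma: no cover - guarded by METHOD_TABLE
        raise ValueError(f"unknown coder {coder!r}")
    k = atoms.shape[1]
    Z = np.zeros((n_vois, k))
    for v in range(n_vois):
        rows = owners == v
        Z[v] = pool_coefficients(
            supports[rows], coefs[rows], n_sel[rows], k, how=pooling
        )
    return Z


def train_method(
    train_set: LabeledDataset,
    config: MethodConfig,
    cache: FeatureCache | None = None,
    dictionary: Dictionary | None = None,
) -> TrainedMethod:
    """Train one method variant on a labeled VOI set.

    Stages: feature extraction -> (z-scoring) -> dictionary learning per the
    method table -> coding -> pooling -> one-against-one SVM.  Fully
    deterministic given the dataset and config seeds.

    A precomputed ``dictionary`` (e.g. shared between SR2/SR3/BOW, whose
    K-Means learning on identical features and seed is identical) skips the
    learning stage; its learner and atom count must match the config.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    t0 = time.perf_counter()
    learner, coder, pooling, kernel = config.components
    log: dict = {"method": config.method}

    X, owners = _dataset_features(train_set, config.patch_size, config.step, cache)
    log["n_features"] = X.shape[0]
    log["t_features"] = time.perf_counter() - t0

    scaler = None
    if config.standardize_features:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    t1 = time.perf_counter()
    if dictionary is not None:
        if dictionary.learner != learner or dictionary.k != config.k_atoms:
            raise ValueError(
                f"precomputed dictionary ({dictionary.learner}, k={dictionary.k}) "
                f"does not match config ({learner}, k={config.k_atoms})"
            )
        log["dictionary_precomputed"] = True
    else:
        kwargs = {} if config.dict_max_iter is None else {"max_iter": config.dict_max_iter}
        if learner == "ksvd":
            dictionary, trace = ksvd(
                X, config.k_atoms, config.T, seed=config.dict_seed, **kwargs
            )
        else:
            dictionary, trace = kmeans_dictionary(
                X, config.k_atoms, seed=config.dict_seed, **kwargs
            )
        log["dictionary_converged"] = trace.converged
    log["t_dictionary"] = time.perf_counter() - t1
    log["dictionary_iterations"] = dictionary.iterations

    t2 = time.perf_counter()
    Z = _encode_and_pool(
        dictionary.atoms, X, owners, len(train_set), coder, pooling, config.T
    )
    log["t_encode"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    model = classify.train_classifier(
        Z, train_set.labels, kernel=kernel, C=config.C, alpha=config.alpha
    )
    log["t_classifier"] = time.perf_counter() - t3
    log["t_total"] = time.perf_counter() - t0
    for stage in ("t_features", "t_dictionary", "t_encode", "t_classifier"):
        logger.info("%s %s: %.2fs", config.method, stage, log[stage])
    return TrainedMethod(
        config=config, dictionary=dictionary, scaler=scaler, classifier=model,
        training_log=log,
    )


def method_descriptors(
    trained: TrainedMethod,
    dataset: LabeledDataset,
    cache: FeatureCache | None = None,
) -> np.ndarray:
    """VOI-level descriptors of a dataset under a trained method."""
    cfg = trained.config
    _, coder, pooling, _ = cfg.components
    X, owners = _dataset_features(dataset, cfg.patch_size, cfg.step, cache)
    if trained.scaler is not None:
        X = trained.scaler.transform(X)
    return _encode_and_pool(
        trained.dictionary.atoms, X, owners, len(dataset), coder, pooling, cfg.T
    )


def predict_method(
    trained: TrainedMethod,
    dataset: LabeledDataset,
    cache: FeatureCache | None = None,
) -> list[str]:
    """Per-VOI predicted labels for a dataset."""
    Z = method_descriptors(trained, dataset, cache)
    return classify.predict(trained.classifier, Z)


def apply_method(
    trained: TrainedMethod,
    test_set: LabeledDataset,
    cache: FeatureCache | None = None,
) -> classify.EvaluationReport:
    """Classify a test set and return the full evaluation report."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    preds = predict_method(trained, test_set, cache)
    return classify.evaluate(preds, test_set.labels)


def nearest_class_mean_baseline(
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    patch_size: int = 3,
    step: int = 4,
    cache: FeatureCache | None = None,
) -> list[str]:
    """Distance-to-class-mean baseline on VOI-level mean feature vectors.

    Each VOI is summarized by the mean of its 16-D local features (z-scored
    with training statistics); a test VOI takes the label of the nearest
    class centroid.  A deliberately weak reference the learned methods are
    expected to beat.
    """
    Xtr, otr = _dataset_features(train_set, patch_size, step, cache)
    Xte, ote = _dataset_features(test_set, patch_size, step, cache)
    scaler = StandardScaler().fit(Xtr)
    Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    mtr = np.stack([Xtr[otr == v].mean(axis=0) for v in range(len(train_set))])
    mte = np.stack([Xte[ote == v].mean(axis=0) for v in range(len(test_set))])
    labels = np.asarray(train_set.labels)
    classes = sorted(set(train_set.labels))
    centroids = np.stack([mtr[labels == c].mean(axis=0) for c in classes])
    d = np.linalg.norm(mte[:, None, :] - centroids[None, :, :], axis=2)
    return [classes[j] for j in np.argmin(d, axis=1)]


def _grid_points(grids: dict) -> list[dict]:
    keys = list(grids)
    return [dict(zip(keys, vals)) for vals in product(*(grids[k] for k in keys))]


def grid_search(
    train_set: LabeledDataset,
    method: str,
    grids: dict | None = None,
    folds: int = 20,
    seed: int = 0,
    base_config: MethodConfig | None = None,
) -> tuple[MethodConfig, pd.DataFrame]:
    """Pick hyperparameters by stratified k-fold cross-validation.

    Every grid point is scored by mean CV overall accuracy; the argmax wins,
    with ties going to smaller k_atoms, then smaller T, then smaller C.
    Configurations that are infeasible (e.g. a dictionary smaller than the
    feature dimension) are recorded with accuracy NaN and skipped.
    Local features are cached per patch size — they do not depend on k/T/C.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if grids is None:
        grids = FULL_GRIDS["BOW" if method == "BOW" else "SR"]
    points = _grid_points(grids)
    if not points:
        raise ValueError("empty parameter grid")
    labels = np.asarray(train_set.labels)
    _, counts = np.unique(labels, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count ({counts.min()}); "
            "reduce folds or add data"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_pairs = list(skf.split(np.zeros(len(labels)), labels))
    base = base_config or MethodConfig(method=method)
    cache = FeatureCache()
    subsets = {}  # fold index -> (train subset, val subset), reused across points
    for f, (tr_idx, va_idx) in enumerate(fold_pairs):
        subsets[f] = (train_set.subset(tr_idx), train_set.subset(va_idx))

    records = []
    for point in points:
        cfg = replace(base, method=method, **point)
        accs = []
        try:
            for f in range(len(fold_pairs)):
                tr_sub, va_sub = subsets[f]
                trained = train_method(tr_sub, cfg, cache=cache)
                report = apply_method(trained, va_sub, cache=cache)
                accs.append(report.accuracy)
            acc = float(np.mean(accs))
        except ValueError as err:
            logger.warning("grid point %s infeasible: %s", point, err)
            acc = float("nan")
        records.append({**point, "cv_accuracy": acc})
    table = pd.DataFrame(records)
    valid = table.dropna(subset=["cv_accuracy"])
    if valid.empty:
        raise ValueError("no feasible configuration in the grid")
    order = valid.sort_values(
        by=["cv_accuracy", "k_atoms", "T", "C"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    best = order.iloc[0]
    best_cfg = replace(
        base, method=method,
        **{key: best[key] if not isinstance(base.__dict__[key], int) else int(best[key])
           for key in grids},
    )
    return best_cfg, table


def compare_methods(predictions: dict[str, list[str]], truth) -> pd.DataFrame:
    """Pairwise McNemar exact p-values between methods on one test set.

    Returns a symmetric DataFrame with NaN on the diagonal (a method is not
    compared with itself).
    """
    names = list(predictions)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = classify.mcnemar_test(predictions[a], predictions[b], truth).p_exact
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat


__all__ = [
    "FULL_GRIDS",
    "METHOD_TABLE",
    "METHODS",
    "FeatureCache",
    "MethodConfig",
    "REDUCED_GRIDS",
    "TrainedMethod",
    "apply_method",
    "compare_methods",
    "grid_search",
    "method_descriptors",
    "nearest_class_mean_baseline",
    "predict_method",
    "train_method",
]
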