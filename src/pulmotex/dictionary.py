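"""Overcomplete dictionary learning by K-SVD or K-Means.

Both learners minimise (different relaxations of) the sparse-approximation
objective  sum_i || y_i - D a_i ||_2^2  subject to  ||a_i||_0 <= T,
over an n x k dictionary D with k > n unit-norm atoms.

K-SVD alternates a sparse-coding stage (OMP at sparsity T on every example)
with a dictionary-update stage that sweeps the atoms in sequence: for atom j
the examples whose support contains j are collected, the residual excluding
atom j's contribution is formed, and its rank-1 SVD provides the new atom
(first left-singular vector) and its coefficients (scaled first
right-singular vector).  Atoms that no example uses are replaced by the
currently worst-represented example, as are near-duplicate atoms
(absolute mutual coherence above a threshold): duplicates trap two atoms on
one direction and stall recovery of the remaining structure.

K-Means is the sparsity-1, coefficient-1 degenerate case: plain Lloyd
iterations, with final centroids l2-normalized so the result satisfies the
unit-norm dictionary contract expected by the OMP coders.

Fixed seeds give bit-identical dictionaries across runs on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import batch_omp
from .features import FeatureMatrix

#: Default K-SVD iteration cap and relative-improvement stopping tolerance.
KSVD_MAX_ITER = 50
KSVD_REL_TOL = 1e-4


@dataclass
class Dictionary:
    """n x k matrix of unit-norm atoms with learning provenance."""

    atoms: np.ndarray
    learner: str = "ksvd"
    iterations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be an (n, k) matrix")
        n, k = self.atoms.shape
        if k <= n:
            raise ValueError(
                f"dictionary must be overcomplete (k > n), got n={n}, k={k}"
            )
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("every atom must have unit l2 norm (within 1e-10)")

    @property
    def n(self) -> int:
        return self.atoms.shape[0]

    @property
    def k(self) -> int:
        return self.atoms.shape[1]


@dataclass
class LearningTrace:
    """Per-iteration objective values and housekeeping events."""

    objective: list[float] = field(default_factory=list)
    post_update_objective: list[float] = field(default_factory=list)
    replacements: list[tuple[int, int]] = field(default_factory=list)  # (iteration, atom)
    converged: bool = False


def _rows_of(features) -> np.ndarray:
    X = np.asarray(getattr(features, "rows", features), dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a nonempty (m, n) matrix")
    return X


def _sample_rows(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k distinct, nonzero rows of X, sampled without replacement."""
    uniq = np.unique(X, axis=0)
    uniq = uniq[np.linalg.norm(uniq, axis=1) > 0]
    if uniq.shape[0] < k:
        raise ValueError(
            f"need at least {k} distinct nonzero feature rows, found {uniq.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(uniq.shape[0], size=k, replace=False)
    return uniq[idx]


def init_dictionary(features, k: int, seed: int = 0) -> Dictionary:
    """Initialize a dictionary from k distinct data rows, normalized."""
    X = _rows_of(features)
    n = X.shape[1]
    if k <= n:
        raise ValueError(f"dictionary must be overcomplete (k > n), got k={k}, n={n}")
    rows = _sample_rows(X, k, seed)
    atoms = rows.T / np.linalg.norm(rows, axis=1)
    return Dictionary(atoms=atoms, learner="init", iterations=0, seed=seed)


def _objective(X: np.ndarray, atoms: np.ndarray, supports, coefs, n_sel) -> float:
    recon = np.zeros_like(X)
    T = supports.shape[1]
    for t in range(T):
        live = n_sel > t
        if not np.any(live):
            break
        recon[live] += coefs[live, t, None] * atoms[:, supports[live, t]].T
    d = X - recon
    return float(np.sum(d * d))


def ksvd(
    features,
    k: int,
    T: int,
    max_iter: int = KSVD_MAX_ITER,
    seed: int = 0,
    tol: float = KSVD_REL_TOL,
    min_usage: int = 1,
    duplicate_coherence: float = 0.95,
) -> tuple[Dictionary, LearningTrace]:
    """Learn a dictionary by K-SVD.

    Parameters
    ----------
    features : FeatureMatrix or (m, n) array
        Training examples, one per row.
    k : int
        Number of atoms; must exceed the feature dimension n.
    T : int
        Sparsity bound used in the OMP coding stage; T <= n.
    max_iter, tol :
        Stop after ``max_iter`` iterations or when the coding-stage objective
        improves by less than ``tol`` relative to its previous value.

    Returns the learned Dictionary and a LearningTrace whose ``objective``
    holds the coding-stage objective per iteration and whose
    ``post_update_objective`` holds the objective recomputed after the
    dictionary-update sweep with the supports fixed (never larger than the
    coding-stage value, by rank-1 SVD optimality).
    """
    X = _rows_of(features)
    m, n = X.shape
    if T > n:
        raise ValueError(f"sparsity T={T} exceeds feature dimension n={n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    atoms = init_dictionary(X, k, seed).atoms.copy()
    trace = LearningTrace()
    prev_obj = np.inf
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        # --- sparse-coding stage ---
        supports, coefs, n_sel, res = batch_omp(atoms, X, T)
        obj = float(np.sum(res * res))
        trace.objective.append(obj)
        # reconstruction of every example, kept in sync during the sweep
        recon = _recon(atoms, supports, coefs, n_sel)
        # --- dictionary-update stage: sweep atoms in sequence ---
        member_lists = _members(supports, n_sel, k)
        for j in range(k):
            members, slots = member_lists[j]
            if members.size == 0:
                continue
            contrib = coefs[members, slots, None] * atoms[:, j][None, :]
            E = (X[members] - recon[members] + contrib).T  # (n, |members|)
            U, S, Vt = np.linalg.svd(E, full_matrices=False)
            u = U[:, 0]
            v = S[0] * Vt[0]
            if u @ atoms[:, j] < 0:  # deterministic sign convention
                u, v = -u, -v
            atoms[:, j] = u
            coefs[members, slots] = v
            recon[members] += (v[:, None] * u[None, :]) - contrib
        # objective with the coding-stage supports after the SVD sweep,
        # before cleanup perturbs any still-referenced duplicate atom
        post = _objective(X, atoms, supports, coefs, n_sel)
        trace.post_update_objective.append(post)
        # --- dictionary cleanup: replace unused and near-duplicate atoms ---
        # (standard K-SVD housekeeping; duplicates trap two atoms on one
        # generating direction and stall recovery of the remainder)
        dead = [j for j in range(k) if member_lists[j][0].size < min_usage]
        gram = np.abs(atoms.T @ atoms)
        np.fill_diagonal(gram, 0.0)
        for j in range(k):
            if j in dead:
                continue
            if any(gram[j, i] > duplicate_coherence for i in range(j)):
                dead.append(j)
        if dead:
            res_now = np.linalg.norm(X - recon, axis=1)
            worst = np.argsort(-res_now, kind="stable")
            wi = 0
            for j in sorted(dead):
                while wi < m and np.linalg.norm(X[worst[wi]]) == 0:
                    wi += 1
                if wi >= m:
                    break
                atoms[:, j] = X[worst[wi]] / np.linalg.norm(X[worst[wi]])
                trace.replacements.append((it, j))
                wi += 1
        if prev_obj < np.inf and prev_obj > 0 and (prev_obj - obj) / prev_obj < tol:
            trace.converged = True
            break
        prev_obj = obj
    return (
        Dictionary(atoms=atoms, learner="ksvd", iterations=iterations, seed=seed),
        trace,
    )


def _recon(atoms, supports, coefs, n_sel) -> np.ndarray:
    m = supports.shape[0]
    recon = np.zeros((m, atoms.shape[0]))
    for t in range(supports.shape[1]):
        live = n_sel > t
        if not np.any(live):
            break
        recon[live] += coefs[live, t, None] * atoms[:, supports[live, t]].T
    return recon


def _members(supports, n_sel, k):
    """For each atom j: (example indices using j, their slot in the support)."""
    m, T = supports.shape
    rows, slots = np.nonzero(np.arange(T)[None, :] < n_sel[:, None])
    flat_atoms = supports[rows, slots]
    order = np.argsort(flat_atoms, kind="stable")
    rows, slots, flat_atoms = rows[order], slots[order], flat_atoms[order]
    bounds = np.searchsorted(flat_atoms, np.arange(k + 1))
    return [
        (rows[bounds[j] : bounds[j + 1]], slots[bounds[j] : bounds[j + 1]])
        for j in range(k)
    ]


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids with D^2 sampling."""
    m = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(m)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centroids
            centroids[j:] = X[rng.choice(m, size=k - j)]
            break
        centroids[j] = X[rng.choice(m, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
    return centroids


def kmeans_dictionary(
    features,
    k: int,
    max_iter: int = 100,
    seed: int = 0,
    normalize: bool = True,
    tol: float = 1e-4,
) -> tuple[Dictionary, LearningTrace]:
    """Learn a dictionary by Lloyd's K-Means on the feature rows.

    Centroids are seeded by k-means++ (D^2 sampling, deterministic given the
    seed), then refined by standard Lloyd iterations — nearest-centroid
    assignment by Euclidean distance (ties to the lowest centroid index),
    centroid = mean of assigned points — with empty clusters reseeded from
    the point farthest from its centroid.  Iteration stops when the
    assignment is unchanged, when the within-cluster objective improves by
    less than ``tol`` relative to its previous value, or at ``max_iter``.
    The trace records the objective after every update, which is
    non-increasing.

    Final centroids are l2-normalized by default so the result satisfies the
    unit-norm dictionary contract expected by the coders; ``normalize=False``
    keeps raw centroids (for sensitivity checks) and skips the unit-norm
    validation.
    """
    X = _rows_of(features)
    m, n = X.shape
    if k <= n:
        raise ValueError(f"dictionary must be overcomplete (k > n), got k={k}, n={n}")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct feature rows")
    centroids = _kmeanspp_init(X, k, np.random.default_rng(seed))
    trace = LearningTrace()
    assign = np.full(m, -1, dtype=np.intp)
    x_sq = np.sum(X * X, axis=1)
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        d2 = x_sq[:, None] - 2.0 * (X @ centroids.T) + np.sum(centroids * centroids, axis=1)[None, :]
        new_assign = np.argmin(d2, axis=1).astype(np.intp)
        point_d2 = np.maximum(d2[np.arange(m), new_assign], 0.0)
        # reseed empty clusters from the globally farthest point
        counts = np.bincount(new_assign, minlength=k)
        empties = np.flatnonzero(counts == 0)
        if empties.size:
            order = np.argsort(-point_d2, kind="stable")
            for rank, j in enumerate(empties):
                p = order[rank]
                centroids[j] = X[p]
                new_assign[p] = j
                point_d2[p] = 0.0
                trace.replacements.append((it, int(j)))
        changed = not np.array_equal(new_assign, assign)
        assign = new_assign
        # update step: centroid = mean of assigned points
        sums = np.zeros((k, n))
        np.add.at(sums, assign, X)
        counts = np.bincount(assign, minlength=k).astype(float)
        new_centroids = sums / np.maximum(counts, 1.0)[:, None]
        new_centroids[counts == 0] = centroids[counts == 0]  # keep orphaned centroids
        centroids = new_centroids
        d2 = x_sq - 2.0 * np.sum(X * centroids[assign], axis=1) + np.sum(
            centroids[assign] * centroids[assign], axis=1
        )
        trace.objective.append(float(np.sum(np.maximum(d2, 0.0))))
        if not changed:
            trace.converged = True
            break
        if (
            len(trace.objective) >= 2
            and trace.objective[-2] > 0
            and (trace.objective[-2] - trace.objective[-1]) < tol * trace.objective[-2]
        ):
            trace.converged = True
            break
    if normalize:
        norms = np.maximum(np.linalg.norm(centroids, axis=1), np.finfo(float).tiny)
        atoms = (centroids / norms[:, None]).T
        d = Dictionary(atoms=atoms, learner="kmeans", iterations=iterations, seed=seed)
    else:
        d = Dictionary.__new__(Dictionary)  # bypass the unit-norm invariant
        d.atoms = np.asarray(centroids.T, dtype=np.float64)
        d.learner = "kmeans"
        d.iterations = iterations
        d.seed = seed
    return d, trace


def save_dictionary(dictionary: Dictionary, path, trace: LearningTrace | None = None) -> None:
    """Persist atoms as .npy with a JSON text sidecar of provenance."""
    import json
    from pathlib import Path

    path = Path(path)
    np.save(path.with_suffix(".npy"), dictionary.atoms)
    meta = {
        "learner": dictionary.learner,
        "n": dictionary.n,
        "k": dictionary.k,
        "iterations": dictionary.iterations,
        "seed": dictionary.seed,
    }
    if trace is not None:
        meta["objective"] = trace.objective
        meta["converged"] = trace.converged
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_dictionary(path) -> Dictionary:
    import json
    from pathlib import Path

    path = Path(path)
    atoms = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return Dictionary(
        atoms=atoms,
        learner=meta["learner"],
        iterations=meta["iterations"],
        seed=meta["seed"],
    )


__all__ = [
    "Dictionary",
    "KSVD_MAX_ITER",
    "KSVD_REL_TOL",
    "LearningTrace",
    "init_dictionary",
    "kmeans_dictionary",
    "ksvd",
    "load_dictionary",
    "save_dictionary",
]
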