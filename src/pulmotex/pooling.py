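"""Spatial pooling: collapse the sparse codes of one VOI's local features
into a single k-dimensional VOI-level descriptor.

Average pooling takes the elementwise mean of the coefficient vectors,
z_t = (1/m) sum_i a_it.  The bag-of-words histogram counts hard assignments
per atom and l1-normalizes; for hard-assign codes (single atom, coefficient
1) the two pooled vectors coincide exactly, which is the formal sense in
which bag-of-words is the sparsity-1 special case of the sparse pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import SparseCode


@dataclass
class Descriptor:
    """One VOI-level vector of length k, input to the classifier."""

    values: np.ndarray
    pooling: str  # "average" | "bow_histogram"
    source_voi: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    @property
    def k(self) -> int:
        return self.values.shape[0]


def _coef_matrix(codes: list[SparseCode]) -> np.ndarray:
    if not codes:
        raise ValueError("cannot pool an empty list of codes")
    k = codes[0].coefficients.shape[0]
    for c in codes:
        if c.coefficients.shape[0] != k:
            raise ValueError(
                f"codes have mixed dictionary sizes: {k} vs {c.coefficients.shape[0]}"
            )
    return np.stack([c.coefficients for c in codes])


def average_pool(codes: list[SparseCode], source_voi: str = "") -> Descriptor:
    """Elementwise mean of the coefficient vectors: z_t = (1/m) sum_i a_it."""
    A = _coef_matrix(codes)
    return Descriptor(values=A.mean(axis=0), pooling="average", source_voi=source_voi)


def bow_histogram(codes: list[SparseCode], k: int, source_voi: str = "") -> Descriptor:
    """l1-normalized histogram of hard assignments over the k atoms.

    Every code must be a hard assignment (single-atom support, coefficient 1).
    """
    if not codes:
        raise ValueError("cannot pool an empty list of codes")
    counts = np.zeros(k)
    for c in codes:
        if len(c.support) != 1 or not np.isclose(c.coefficients[c.support[0]], 1.0):
            raise ValueError(
                "bag-of-words pooling requires hard-assign codes "
                "(|support| = 1, coefficient 1)"
            )
        counts[c.support[0]] += 1.0
    return Descriptor(
        values=counts / len(codes), pooling="bow_histogram", source_voi=source_voi
    )


def pool_coefficients(supports, coefs, n_sel, k, how: str = "average") -> np.ndarray:
    """Array fast path used by the pipeline: pool one VOI's batch-coder output.

    Identical to building SparseCode objects and calling
    :func:`average_pool` / :func:`bow_histogram` (asserted in tests).
    """
    m = supports.shape[0]
    z = np.zeros(k)
    if how == "average":
        for t in range(supports.shape[1]):
            live = n_sel > t
            if not np.any(live):
                break
            np.add.at(z, supports[live, t], coefs[live, t])
        return z / m
    if how == "bow_histogram":
        np.add.at(z, supports[:, 0], 1.0)
        return z / m
    raise ValueError(f"unknown pooling {how!r}")


__all__ = ["Descriptor", "average_pool", "bow_histogram", "pool_coefficients"]
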