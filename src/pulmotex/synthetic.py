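"""Synthetic VOI generator for the six pulmonary texture patterns.

Clinical HRCT volumes of interest are not redistributable, so this module
emulates the six classes on an arbitrary linear intensity scale (roughly
air ~ 0, aerated parenchyma ~ 100, soft tissue ~ 400):

* NOR — homogeneous low-attenuation parenchyma (Gaussian background).
* CON — homogeneous high-attenuation consolidation.
* GGO — intermediate attenuation with a smooth low-frequency haze.
* EMP — parenchyma punched by dark quasi-spherical holes (air traps).
* NOD — parenchyma with bright quasi-spherical blobs (nodular opacities).
* HCM — bright honeycomb walls (Voronoi-cell boundaries) over dark cells.

The module also produces exact sparse-signal datasets from known random
dictionaries, used to validate the sparse-approximation solvers.
All randomness flows through ``numpy.random.default_rng(seed)``; identical
(spec, seed) pairs give bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .volume import PATTERN_LABELS, VOI_SHAPE, LabeledDataset, Volume, check_label

#: Intensity all class means are pulled towards when the separation knob
#: shrinks; roughly the centre of the synthetic attenuation range.
_SEPARATION_CENTER = 150.0

#: Per-class defaults: base mean/sd of the background, the smoothing sigma
#: that introduces spatial autocorrelation, and geometry parameters.
#: The structural classes (EMP, NOD, HCM) share the normal-parenchyma
#: background attenuation and are distinguished by geometry, as on real
#: HRCT, where attenuation alone cannot separate them; only consolidation
#: and ground-glass opacity shift the background itself.  Count entries
#: given as (lo, hi) ranges are drawn per VOI by :func:`default_spec`,
#: emulating the clinical variability in the number of nodular opacities
#: or air traps per VOI.
_CLASS_DEFAULTS: dict[str, dict] = {
    "NOR": dict(base_mean=100.0, base_sd=15.0, smooth_sigma=0.5, structure={}),
    "CON": dict(base_mean=400.0, base_sd=30.0, smooth_sigma=0.8, structure={}),
    "GGO": dict(
        base_mean=170.0,
        base_sd=15.0,
        smooth_sigma=0.5,
        structure=dict(haze_amplitude=35.0, haze_sigma=4.0),
    ),
    "EMP": dict(
        base_mean=100.0,
        base_sd=15.0,
        smooth_sigma=0.5,
        structure=dict(n_holes=(6, 14), radius_range=(2.0, 4.0), hole_value=0.0),
    ),
    "NOD": dict(
        base_mean=100.0,
        base_sd=15.0,
        smooth_sigma=0.5,
        structure=dict(n_blobs=(3, 9), radius_range=(2.0, 4.0), blob_value=350.0),
    ),
    "HCM": dict(
        base_mean=70.0,  # dark cell interior
        base_sd=15.0,
        smooth_sigma=0.5,
        structure=dict(n_cells=(18, 30), wall_thickness=1.2, wall_value=330.0),
    ),
}

#: Additive noise sd painted on blobs/holes/walls so structures are not flat.
_STRUCTURE_NOISE_SD = 5.0


@dataclass
class PatternSpec:
    """Recipe for one synthetic VOI of a given pulmonary pattern."""

    pattern_label: str
    base_mean: float
    base_sd: float
    structure_params: dict = field(default_factory=dict)
    smooth_sigma: float = 0.0
    seed: int = 0
    shape: tuple[int, int, int] = VOI_SHAPE

    def __post_init__(self) -> None:
        check_label(self.pattern_label)
        if self.base_sd < 0:
            raise ValueError(f"base_sd must be >= 0, got {self.base_sd}")
        for key in ("n_holes", "n_blobs", "n_cells"):
            if key in self.structure_params and self.structure_params[key] <= 0:
                raise ValueError(f"{key} must be strictly positive")
        rr = self.structure_params.get("radius_range")
        if rr is not None and (rr[0] <= 0 or rr[1] < rr[0]):
            raise ValueError(f"invalid radius_range {rr}")


def default_spec(label: str, seed: int = 0, separation: float = 1.0) -> PatternSpec:
    """Default PatternSpec for a class, with a class-separability knob.

    ``separation`` linearly rescales every class-specific intensity about a
    common centre: 1.0 gives the standard well-separated classes, 0.0
    collapses all class means onto one value (geometry is kept, contrast
    vanishes).  Increasing it can only make classes easier to tell apart.

    Structure counts listed as (lo, hi) ranges in the class defaults are
    drawn uniformly (inclusive) from the spec's seed, so the number of
    blobs/holes/cells varies from VOI to VOI but is reproducible.
    """
    check_label(label)
    d = _CLASS_DEFAULTS[label]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))

    def pull(v: float) -> float:
        return _SEPARATION_CENTER + separation * (v - _SEPARATION_CENTER)

    structure = dict(d["structure"])
    for key in ("n_holes", "n_blobs", "n_cells"):
        if key in structure and isinstance(structure[key], tuple):
            lo, hi = structure[key]
            structure[key] = int(rng.integers(lo, hi + 1))
    for key in ("hole_value", "blob_value", "wall_value"):
        if key in structure:
            structure[key] = pull(structure[key])
    if "haze_amplitude" in structure:
        structure["haze_amplitude"] = separation * structure["haze_amplitude"]
    return PatternSpec(
        pattern_label=label,
        base_mean=pull(d["base_mean"]),
        base_sd=d["base_sd"],
        structure_params=structure,
        smooth_sigma=d["smooth_sigma"],
        seed=seed,
    )


def _place_spheres(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n: int,
    radius_range: tuple[float, float],
    min_gap: float = 2.0,
    max_tries: int = 20000,
) -> list[tuple[np.ndarray, float]]:
    """Rejection-sample non-overlapping sphere (center, radius) pairs.

    Spheres are kept fully inside the volume and pairwise separated by at
    least ``min_gap`` voxels of surface distance, so they remain distinct
    connected components after thresholding.
    """
    placed: list[tuple[np.ndarray, float]] = []
    lo, hi = radius_range
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping spheres of radius "
                f"{radius_range} in volume {shape}; reduce count or radius"
            )
        r = rng.uniform(lo, hi)
        center = np.array([rng.uniform(r + 1, s - r - 1) for s in shape])
        if all(
            np.linalg.norm(center - c) >= r + rc + min_gap for c, rc in placed
        ):
            placed.append((center, r))
    return placed


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def generate_pattern_voi(spec: PatternSpec) -> Volume:
    """Generate one synthetic VOI according to a PatternSpec.

    The background is i.i.d. Gaussian noise, optionally smoothed by a small
    Gaussian kernel (``smooth_sigma``) to introduce autocorrelation;
    class-specific structures are painted on top of the smoothed background
    so their geometry stays crisp.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    vox = rng.normal(spec.base_mean, spec.base_sd, size=shape)
    if spec.smooth_sigma > 0:
        vox = spec.base_mean + gaussian_filter(
            vox - spec.base_mean, spec.smooth_sigma, mode="reflect"
        )

    p = spec.structure_params
    label = spec.pattern_label
    if label == "GGO" and p.get("haze_amplitude", 0) > 0:
        haze = gaussian_filter(
            rng.standard_normal(shape), p.get("haze_sigma", 4.0), mode="reflect"
        )
        sd = haze.std()
        if sd > 0:
            vox += p["haze_amplitude"] * haze / sd
    elif label == "EMP":
        for center, r in _place_spheres(
            rng, shape, int(p["n_holes"]), tuple(p["radius_range"])
        ):
            mask = _sphere_mask(shape, center, r)
            vox[mask] = p["hole_value"] + rng.normal(
                0.0, _STRUCTURE_NOISE_SD, int(mask.sum())
            )
    elif label == "NOD":
        for center, r in _place_spheres(
            rng, shape, int(p["n_blobs"]), tuple(p["radius_range"])
        ):
            mask = _sphere_mask(shape, center, r)
            vox[mask] = p["blob_value"] + rng.normal(
                0.0, _STRUCTURE_NOISE_SD, int(mask.sum())
            )
    elif label == "HCM":
        seeds = rng.uniform(0, np.array(shape), size=(int(p["n_cells"]), 3))
        coords = np.stack(
            np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        dists, _ = cKDTree(seeds).query(coords, k=2)
        wall = (dists[:, 1] - dists[:, 0]) < p["wall_thickness"]
        wall = wall.reshape(shape)
        vox[wall] = p["wall_value"] + rng.normal(
            0.0, _STRUCTURE_NOISE_SD, int(wall.sum())
        )
    # CON and NOR are pure background.

    return Volume(voxels=vox, spacing=(1.0, 1.0, 1.0), identifier=f"{label}_seed{spec.seed}")


def generate_dataset(
    class_counts: dict[str, int],
    seed: int = 0,
    separation: float = 1.0,
    split: str = "",
) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate a labeled synthetic dataset with exact per-class counts.

    VOIs are generated in vocabulary order (CON, GGO, ..., NOR), each from
    an independent per-VOI seed derived from ``seed``, so the manifest
    depends only on the counts while the voxel data depend on the seed.

    Returns the dataset and a manifest DataFrame with columns
    (voi_path, label, split); ``voi_path`` holds the VOI identifier until
    the dataset is written to disk by :func:`pulmotex.io.save_dataset`.
    """
    for label, count in class_counts.items():
        check_label(label)
        if count < 0:
            raise ValueError(f"count for {label} must be >= 0, got {count}")
    total = sum(class_counts.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1), dtype=np.uint32)

    volumes: list[Volume] = []
    labels: list[str] = []
    rows = []
    i = 0
    for label in PATTERN_LABELS:
        for j in range(class_counts.get(label, 0)):
            spec = default_spec(label, seed=int(child_seeds[i] % (2**31)), separation=separation)
            vol = generate_pattern_voi(spec)
            vol.identifier = f"{label}_{j:04d}"
            volumes.append(vol)
            labels.append(label)
            rows.append({"voi_path": vol.identifier, "label": label, "split": split})
            i += 1
    manifest = pd.DataFrame(rows, columns=["voi_path", "label", "split"])
    tags = [split] * total if split else None
    return LabeledDataset(volumes=volumes, labels=labels, split_tags=tags), manifest


@dataclass
class SparseSignalSet:
    """Signals that are exact T0-sparse combinations of a known dictionary."""

    true_dictionary: np.ndarray  # (n, k), unit-norm columns
    true_codes: np.ndarray  # (m, k), each row exactly T0-sparse
    signals: np.ndarray  # (m, n)
    noise_sd: float
    T0: int
    seed: int


def generate_sparse_signals(
    n: int,
    k: int,
    m: int,
    T0: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SparseSignalSet:
    """Draw a random unit-norm dictionary and m exact T0-sparse signals.

    Atoms are i.i.d. standard-Gaussian columns normalized to unit l2 norm.
    Each signal's support is drawn uniformly without replacement; nonzero
    coefficients are uniform in magnitude on [0.5, 1.5] with random sign, so
    no coefficient is vanishingly small.  ``signals = codes @ D.T + noise``
    exactly, given the seed.
    """
    if not (T0 <= n < k):
        raise ValueError(
            f"need sparsity T0 <= n < k (overcomplete dictionary); "
            f"got T0={T0}, n={n}, k={k}"
        )
    if m < 1:
        raise ValueError(f"need at least one signal, got m={m}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((n, k))
    D /= np.linalg.norm(D, axis=0, keepdims=True)
    codes = np.zeros((m, k))
    for i in range(m):
        support = rng.choice(k, size=T0, replace=False)
        mags = rng.uniform(0.5, 1.5, size=T0)
        signs = rng.choice([-1.0, 1.0], size=T0)
        codes[i, support] = mags * signs
    signals = codes @ D.T
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return SparseSignalSet(
        true_dictionary=D,
        true_codes=codes,
        signals=signals,
        noise_sd=noise_sd,
        T0=T0,
        seed=seed,
    )


__all__ = [
    "PatternSpec",
    "SparseSignalSet",
    "default_spec",
    "generate_dataset",
    "generate_pattern_voi",
    "generate_sparse_signals",
]
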