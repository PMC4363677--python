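# Methods

## Problem and model

`pulmotex` classifies 32×32×32-voxel volumes of interest (VOIs) from chest
HRCT into six texture classes: consolidation (CON), ground-glass opacity
(GGO), honeycombing (HCM), emphysema (EMP), nodule (NOD) and normal
parenchyma (NOR). Every method variant shares one skeleton:

1. **Local features.** On a regular lattice (stride 4 per axis) a cubic
   patch is read from four volumes — the raw intensities and the three
   voxelwise Hessian-eigenvalue fields λ₁ ≥ λ₂ ≥ λ₃ — and four population
   moments (mean, sd, skewness, non-excess kurtosis) are computed on each,
   giving a 16-vector per sampling point. Intensity moments carry
   attenuation; eigenvalue moments carry local second-order geometry
   (blob/tube/plate structure).
2. **Overcomplete dictionary.** The training features y_i ∈ ℝ¹⁶ are
   approximated by D a_i with D ∈ ℝ^{n×k}, k ≫ n, unit-norm atoms, under the
   sparsity constraint ‖a_i‖₀ ≤ T, i.e. minimising Σᵢ‖y_i − D a_i‖₂²
   subject to ‖a_i‖₀ ≤ T. The dictionary is learned by K-SVD or by K-Means.
3. **Sparse coding.** Per feature vector, coefficients come from greedy OMP,
   from the one-pass variant OMP₁ (rank all atoms by |⟨d_j, y⟩| once, take
   the top T, one least-squares fit), or from hard nearest-atom assignment.
4. **Spatial pooling.** The VOI descriptor is the elementwise average of its
   codes, z_t = (1/m) Σᵢ a_{it}; for hard assignments this equals the
   ℓ₁-normalised atom histogram, which is why bag-of-words (BOW) is exactly
   the sparsity-1, coefficient-1 special case.
5. **Classification.** One-against-one soft-margin SVMs (q(q−1)/2 binary
   machines, majority vote) with the linear kernel x_i^T x_j for averaged
   sparse codes, or the exponential χ² kernel
   exp[−α Σ_t (x_{it}−x_{jt})²/(x_{it}+x_{jt})] for BOW histograms.

The four variants are SR1 = K-SVD + OMP, SR2 = K-Means + OMP,
SR3 = K-Means + OMP₁, BOW = K-Means + hard assignment + χ² SVM. SR2 and
SR3 trade a little coding optimality for large runtime reductions in
dictionary learning and per-VOI coding respectively; the package's
benchmark measures both trade-offs.

## Numerical conventions

These are fixed so that unit tests can be exact:

* **Hessian**: second-order central finite differences on the raw volume,
  replicate padding at boundaries; diagonal entries use f[i+1]−2f[i]+f[i−1],
  mixed entries apply the first-difference operator twice. Exact on
  quadratics; no Gaussian pre-smoothing (none is assumed by the feature
  definition, and omitting it keeps clean oracles). Eigenvalues from a
  symmetric 3×3 eigensolver, sorted descending by signed value.
* **Patch convention**: a patch of size s at centre c spans
  [c−⌊s/2⌋, c−⌊s/2⌋+s) per axis; only centres whose patch lies fully inside
  the volume are sampled, starting at the smallest valid centre, stride 4,
  lexicographic (x, y, z) order. A 32³ VOI at patch 4³/step 4 yields 512
  sampling points.
* **Moments**: population (biased) moments, non-excess kurtosis; a
  zero-variance patch has skewness = kurtosis = 0 by convention, so flat
  patches produce finite features.
* **Tie-breaks**: all atom selections (OMP, OMP₁, hard assignment) and all
  classifier vote ties resolve to the lowest index / earliest class in the
  fixed vocabulary (CON, GGO, HCM, EMP, NOD, NOR). This makes every stage
  bit-reproducible under a fixed seed.
* **Atom selection statistic**: absolute inner product (standard OMP
  practice); signed selection is available behind a flag for ablation.
  Hard assignment uses Euclidean distance, which for unit atoms coincides
  with the largest signed inner product.
* **Least squares**: per-signal solves use QR (``lstsq``); the vectorised
  batch coder solves the Gram normal equations, asserted in tests to match
  the QR path to 1e-10 on the well-conditioned supports OMP selects.
* **K-SVD**: initial atoms are k distinct feature rows, normalised; each
  iteration codes all examples with OMP at sparsity T, then sweeps atoms in
  sequence replacing each by the first left-singular vector of the
  restricted residual (sign fixed towards the previous atom). Dictionary
  cleanup after each sweep replaces unused atoms and near-duplicate atoms
  (absolute mutual coherence > 0.95) with the worst-represented example —
  standard K-SVD housekeeping; without the duplicate rule two atoms can
  lock onto one generating direction and recovery of the remaining
  structure stalls. On the pipeline's real features (k = 256 ≫ n = 16)
  replacements die out within a few iterations, so the threshold does not
  cause churn. Stops at ``max_iter`` (default 50) or relative objective
  improvement < 1e-4 — the stopping rule is an implementation choice,
  exposed in the config.
* **K-Means**: k-means++ seeding (D² sampling, deterministic per seed)
  followed by Lloyd iterations; empty clusters are reseeded from the point
  farthest from its centroid; final centroids are ℓ₂-normalised by default
  so the dictionary contract (unit-norm atoms) holds before OMP/OMP₁
  coding, with a switch to keep raw centroids for sensitivity checks.
* **Feature standardisation**: per-dimension z-scoring with training-set
  statistics, applied before dictionary learning and coding and stored in
  the trained model (default on). The 16 dimensions mix attenuation means
  with dimensionless kurtoses; the sparse-approximation objective presumes
  comparable scales.
* **McNemar's test**: the primary p-value is the exact two-sided binomial
  test on the discordant counts (valid at any count); the continuity-
  corrected χ² approximation is also reported.
* **Cross-validation**: stratified folds (class counts are imbalanced in
  realistic datasets, and unstratified 20-fold splits could lose a class
  from a fold); grid ties resolve to smaller k, then smaller T, then
  smaller C.

## Synthetic data

Clinical VOIs cannot be redistributed, so `pulmotex.synthetic` emulates the
six classes on an arbitrary linear intensity scale (≈ air 0, parenchyma 100,
soft tissue 400 — the pipeline is scale-covariant up to standardisation, so
no HU calibration is claimed):

| class | background mean ± sd | geometry |
|-------|----------------------|----------|
| NOR | 100 ± 15 | none |
| CON | 400 ± 30 | none |
| GGO | 170 ± 15 | smooth low-frequency haze, amplitude 35, σ = 4 |
| EMP | 100 ± 15 | 6–14 dark spherical holes (value 0), radius 2–4 |
| NOD | 100 ± 15 | 3–9 bright spherical blobs (value 350), radius 2–4 |
| HCM | 70 ± 15 (cells) | Voronoi-cell walls (value 330), 18–30 cells, thickness 1.2 |

Backgrounds are i.i.d. Gaussian noise smoothed with a σ = 0.5 kernel
(σ = 0.8 for CON) for spatial autocorrelation; structures are painted after
smoothing so their geometry stays crisp, with ±5 intensity noise. Spheres
are placed by rejection sampling, fully inside the volume and pairwise
non-overlapping, so thresholding oracles can count them. Structure counts
are drawn per VOI from the stated ranges, emulating clinical variability in
the number of nodular opacities or air traps.

Two deliberate design points. First, the structural classes share the
normal-parenchyma background: EMP, NOD and NOR (and largely HCM) cannot be
separated by mean attenuation alone, as on real HRCT, so a
distance-to-class-mean baseline on VOI-mean features is imperfect while the
sparse-descriptor methods, which see the distribution of local patterns,
are near-perfect. Second, a `separation` knob rescales all class-specific
intensities about a common centre; shrinking it collapses contrast while
keeping geometry, and downstream accuracy responds monotonically (tested).

What the generator does **not** emulate: anatomical context (vessels,
airways, fissures), partial-volume mixtures of patterns, scanner noise
spectra, or inter-patient attenuation shifts. Passing the end-to-end tests
therefore demonstrates that the pipeline machinery is correct and that the
method ordering (sparse methods ≥ baseline; variants within a few points of
each other; K-Means/OMP₁ much cheaper) is reproduced — not that the
absolute synthetic accuracies transfer to clinical data.

## Study conditions of the benchmark

`pulmotex.benchmark` fixes the desk-scale conditions used by the acceptance
tests and `scripts/acceptance.py`: 100 training and 100 test VOIs per class
(600 + 600), patch 3³, step 4, k = 256 atoms, T = 2, C = 16, χ² α = 1,
K-SVD capped at 15 iterations, feature standardisation on. These sizes keep
a full four-variant study within minutes on one CPU while leaving every
stage (dictionary learning on ~3×10⁵ feature vectors, coding, pooling,
15 binary SVMs) at realistic aspect ratios. Planted-model experiments use
n = 16, k = 32, T₀ = 3, m = 2000 noiseless signals for K-SVD recovery and
24 well-separated Gaussian clusters for K-Means recovery. Runtime
comparisons are relative on one host and reported only as percentages
(absolute seconds are hardware-dependent): the dictionary-learning
comparison reads the pipeline's own training logs, where SR1 (K-SVD) and
SR2 (K-Means) learn from identical standardised features with the same k
and seed; the coding comparison times the batch coders on identical
signals at k = 1024 atoms and T = 4 (mid-range of the published parameter
grids, where the per-iteration correlation pass dominates), best of three
repeats.

## Known limitations

* Greedy OMP recovers a planted support only when true coefficients
  dominate cross-correlations; the small-instance oracle asserts the
  one-sided bound (greedy ≥ exhaustive optimum), not equality.
* The χ² kernel is used with ℓ₁-normalised histograms; unnormalised counts
  would change the effective α scale.
* K-SVD's iteration count, initialisation and dead-atom rule are standard
  but not canonical; all are seeded and configurable.
* `grid_search` with the full published grids (3150 SR combinations ×
  20 folds) is supported but computationally heavy by design; the CLI
  defaults to reduced grids.
* Volumes other than 32³ are readable and feature-extractable, but the
  pipeline's shape gate rejects them, since the descriptor statistics and
  defaults assume the 32³ geometry.
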