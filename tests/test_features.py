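"""Local-feature layer: Hessian eigenvalues, sampling lattice, patch moments
and the assembled 16-dimensional feature vectors."""

import numpy as np
import pytest
from scipy import stats

import pulmotex as px
from pulmotex.features import (
    FEATURE_DIM,
    extract_features,
    hessian_components,
    hessian_eigen,
    patch_moments,
    sampling_centers,
)
from pulmotex.volume import Volume


class TestHessianEigen:
    def test_constant_volume_all_zero(self):
        eig = hessian_eigen(Volume(np.full((8, 8, 8), 7.0)))
        assert np.abs(eig.lambda1).max() == 0.0
        assert np.abs(eig.lambda3).max() == 0.0

    def test_quadratic_volume_exact(self):
        # f(x,y,z) = x^2: central differences are exact on quadratics, so
        # interior eigenvalues are exactly (2, 0, 0)
        x = np.arange(10, dtype=float)
        vol = np.broadcast_to((x**2)[:, None, None], (10, 10, 10)).copy()
        eig = hessian_eigen(Volume(vol))
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(eig.lambda1[interior], 2.0, atol=1e-12)
        np.testing.assert_allclose(eig.lambda2[interior], 0.0, atol=1e-12)
        np.testing.assert_allclose(eig.lambda3[interior], 0.0, atol=1e-12)

    def test_eigenvalue_sum_equals_hessian_trace(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        eig = hessian_eigen(Volume(vol))
        h = hessian_components(vol)
        trace = h["xx"] + h["yy"] + h["zz"]
        total = eig.lambda1 + eig.lambda2 + eig.lambda3
        np.testing.assert_allclose(total, trace, rtol=1e-9, atol=1e-9)

    def test_sorted_descending_everywhere(self, rng):
        eig = hessian_eigen(Volume(rng.normal(size=(6, 6, 6))))
        assert (eig.lambda1 >= eig.lambda2).all()
        assert (eig.lambda2 >= eig.lambda3).all()

    def test_matches_characteristic_polynomial_oracle(self, rng):
        # independent eigenvalue route: roots of det(H - t I) per voxel
        vol = rng.normal(size=(5, 5, 5))
        h = hessian_components(vol)
        eig = hessian_eigen(Volume(vol))
        got = np.stack(
            [eig.lambda1.ravel(), eig.lambda2.ravel(), eig.lambda3.ravel()], axis=1
        )
        for i in range(vol.size):
            H = np.array(
                [
                    [h["xx"].flat[i], h["xy"].flat[i], h["xz"].flat[i]],
                    [h["xy"].flat[i], h["yy"].flat[i], h["yz"].flat[i]],
                    [h["xz"].flat[i], h["yz"].flat[i], h["zz"].flat[i]],
                ]
            )
            coeffs = np.poly(H)
            roots = np.sort(np.real(np.roots(coeffs)))[::-1]
            np.testing.assert_allclose(got[i], roots, atol=1e-8)


class TestSamplingCenters:
    def test_paper_lattice_has_512_centers(self):
        centers = sampling_centers((32, 32, 32), step=4, patch_size=4)
        assert centers.shape == (512, 3)
        # smallest valid center per axis is patch_size//2 = 2
        assert centers.min() == 2 and centers.max() == 30
        # lexicographic (x, y, z) order
        assert np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0])).tolist() == list(
            range(512)
        )

    def test_single_center_when_step_spans_volume(self):
        assert sampling_centers((32, 32, 32), step=32, patch_size=2).shape == (1, 3)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            sampling_centers((32, 32, 32), step=4, patch_size=64)

    @pytest.mark.parametrize("patch_size", [2, 3, 4, 5, 6])
    def test_every_patch_fits(self, patch_size):
        centers = sampling_centers((32, 32, 32), step=4, patch_size=patch_size)
        half = patch_size // 2
        assert (centers - half >= 0).all()
        assert (centers - half + patch_size <= 32).all()


class TestPatchMoments:
    def test_constant_patch_degenerate_convention(self):
        assert patch_moments(np.full((3, 3, 3), 5.0)) == (5.0, 0.0, 0.0, 0.0)

    def test_two_point_distribution(self):
        # equal numbers of -1 and 1: mean 0, sd 1, skewness 0, kurtosis 1
        patch = np.array([-1.0, 1.0] * 4).reshape(2, 2, 2)
        mean, sd, skew, kurt = patch_moments(patch)
        assert (mean, sd, skew, kurt) == (0.0, 1.0, 0.0, 1.0)

    def test_shift_moves_only_the_mean(self, rng):
        patch = rng.normal(size=(4, 4, 4))
        m0 = patch_moments(patch)
        m1 = patch_moments(patch + 13.5)
        assert m1[0] == pytest.approx(m0[0] + 13.5)
        assert m1[1:] == pytest.approx(m0[1:])

    def test_matches_scipy_population_moments(self, rng):
        patch = rng.normal(size=(5, 5, 5))
        mean, sd, skew, kurt = patch_moments(patch)
        x = patch.ravel()
        assert mean == pytest.approx(x.mean())
        assert sd == pytest.approx(x.std(ddof=0))
        assert skew == pytest.approx(stats.skew(x, bias=True))
        assert kurt == pytest.approx(stats.kurtosis(x, bias=True, fisher=False))


class TestExtractFeatures:
    def test_paper_geometry_gives_512_by_16(self, rng):
        vol = Volume(rng.normal(100, 15, size=(32, 32, 32)))
        fm = extract_features(vol, patch_size=4, step=4)
        assert fm.rows.shape == (512, FEATURE_DIM)

    def test_constant_volume_features(self):
        fm = extract_features(Volume(np.full((32, 32, 32), 42.0)), patch_size=4)
        expected = np.zeros(16)
        expected[0] = 42.0
        np.testing.assert_array_equal(fm.rows, np.tile(expected, (512, 1)))

    def test_deterministic(self, rng):
        vox = rng.normal(size=(32, 32, 32))
        a = extract_features(Volume(vox.copy()), 3)
        b = extract_features(Volume(vox.copy()), 3)
        np.testing.assert_array_equal(a.rows, b.rows)

    def test_intensity_shift_covariance(self, rng):
        # adding c changes only the intensity mean column; the Hessian of a
        # constant is zero so all eigenvalue features are unchanged
        vox = rng.normal(size=(32, 32, 32))
        a = extract_features(Volume(vox), 3).rows
        b = extract_features(Volume(vox + 50.0), 3).rows
        np.testing.assert_allclose(b[:, 0], a[:, 0] + 50.0, atol=1e-9)
        np.testing.assert_allclose(b[:, 1:], a[:, 1:], atol=1e-9)

    def test_shape_gate(self, rng):
        vol = Volume(rng.normal(size=(16, 16, 16)))
        with pytest.raises(ValueError, match="pipeline requires"):
            extract_features(vol, 3, expected_shape=(32, 32, 32))

    def test_moments_agree_with_scalar_path(self, rng):
        # vectorized gather/moment path vs direct per-patch computation
        vox = rng.normal(size=(32, 32, 32))
        vol = Volume(vox)
        fm = extract_features(vol, patch_size=3, step=8)
        eig = hessian_eigen(vol)
        for row, center in zip(fm.rows[:5], fm.centers[:5]):
            sl = tuple(slice(c - 1, c + 2) for c in center)
            expected = []
            for channel in (vox, eig.lambda1, eig.lambda2, eig.lambda3):
                expected.extend(patch_moments(channel[sl]))
            np.testing.assert_allclose(row, expected, atol=1e-12)
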