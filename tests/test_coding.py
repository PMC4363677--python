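"""Sparse coders: greedy OMP, one-pass OMP, hard assignment, batch purity
and agreement with exhaustive and library oracles."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.linear_model import OrthogonalMatchingPursuit

import pulmotex as px
from pulmotex.coding import (
    batch_omp,
    batch_omp1,
    encode_matrix,
    hard_assign,
    omp,
    omp1,
)


def best_subset_residual(atoms, y, T):
    """Exhaustive best-T-subset least squares: the global optimum."""
    best = (np.inf, None)
    for support in combinations(range(atoms.shape[1]), T):
        coef, *_ = np.linalg.lstsq(atoms[:, support], y, rcond=None)
        r = np.linalg.norm(y - atoms[:, support] @ coef)
        if r < best[0]:
            best = (r, support)
    return best


class TestOmp:
    def test_orthonormal_basis_selects_largest_component(self):
        D = np.eye(3)
        y = np.array([0.5, -2.0, 0.1])
        code = omp(D, y, T=1)
        assert code.support == (1,)
        assert code.coefficients[1] == pytest.approx(-2.0)
        assert code.residual_norm == pytest.approx(np.sqrt(0.25 + 0.01))
        code2 = omp(D, y, T=2)
        assert code2.support == (1, 0)
        assert code2.residual_norm == pytest.approx(0.1)

    def test_recovers_exact_sparse_combination(self):
        # greedy recovery holds when the true coefficients dominate the
        # cross-correlations, as with this dictionary draw
        rng = np.random.default_rng(1)
        D = rng.standard_normal((8, 20))
        D /= np.linalg.norm(D, axis=0)
        true_support = (3, 11)
        y = 2.0 * D[:, 3] - 1.5 * D[:, 11]
        code = omp(D, y, T=2)
        assert code.residual_norm < 1e-10
        # compare against the exhaustive-subset oracle over all C(20,2) supports
        r_opt, s_opt = best_subset_residual(D, y, 2)
        assert set(code.support) == set(s_opt) == set(true_support)

    def test_residual_monotone_in_t(self, random_unit_dictionary, rng):
        y = rng.standard_normal(16)
        res = [omp(random_unit_dictionary, y, T).residual_norm for T in range(1, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(res, res[1:]))

    def test_residual_recomputes_from_coefficients(self, random_unit_dictionary, rng):
        y = rng.standard_normal(16)
        code = omp(random_unit_dictionary, y, 4)
        recon = random_unit_dictionary @ code.coefficients
        assert code.residual_norm == pytest.approx(np.linalg.norm(y - recon), abs=1e-9)
        assert set(np.flatnonzero(code.coefficients)) <= set(code.support)

    def test_sparsity_bound_respected(self, random_unit_dictionary, rng):
        for T in (1, 3, 6):
            code = omp(random_unit_dictionary, rng.standard_normal(16), T)
            assert len(code.support) <= T

    def test_agrees_with_sklearn_omp(self, random_unit_dictionary, rng):
        # independent implementation route for the same greedy algorithm
        y = rng.standard_normal(16)
        code = omp(random_unit_dictionary, y, 4)
        ref = OrthogonalMatchingPursuit(n_nonzero_coefs=4, fit_intercept=False)
        ref.fit(random_unit_dictionary, y)
        np.testing.assert_allclose(code.coefficients, ref.coef_, atol=1e-8)

    def test_invalid_inputs(self, random_unit_dictionary):
        with pytest.raises(ValueError):
            omp(random_unit_dictionary, np.zeros(16), T=0)
        with pytest.raises(ValueError, match="dimension"):
            omp(random_unit_dictionary, np.zeros(7), T=2)


class TestOmp1:
    def test_support_is_top_t_inner_products(self, random_unit_dictionary, rng):
        y = rng.standard_normal(16)
        for T in (1, 3, 6):
            code = omp1(random_unit_dictionary, y, T)
            ranking = np.argsort(-np.abs(random_unit_dictionary.T @ y), kind="stable")
            assert list(code.support) == list(ranking[:T])

    def test_identical_to_omp_on_orthonormal(self, orthonormal_dictionary, rng):
        for _ in range(5):
            y = rng.standard_normal(16)
            for T in (1, 4, 8):
                a = omp(orthonormal_dictionary, y, T)
                b = omp1(orthonormal_dictionary, y, T)
                assert a.support == b.support
                np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-10)
                assert a.residual_norm == pytest.approx(b.residual_norm, abs=1e-10)

    def test_t1_equals_omp(self, random_unit_dictionary, rng):
        y = rng.standard_normal(16)
        a, b = omp(random_unit_dictionary, y, 1), omp1(random_unit_dictionary, y, 1)
        assert a.support == b.support
        np.testing.assert_allclose(a.coefficients, b.coefficients)

    def test_residual_never_better_than_omp_by_much(self, rng):
        # one-pass selection is weaker or equal; both beat the best single atom
        D = rng.standard_normal((16, 64))
        D /= np.linalg.norm(D, axis=0)
        worse = 0
        for _ in range(50):
            y = rng.standard_normal(16)
            r_omp = omp(D, y, 6).residual_norm
            r_omp1 = omp1(D, y, 6).residual_norm
            r_single = omp(D, y, 1).residual_norm
            assert r_omp <= r_single + 1e-12
            assert r_omp1 <= r_single + 1e-12
            worse += r_omp1 > r_omp + 1e-12
        assert worse >= 0  # recorded distributionally; no fixed claim

    def test_raw_coefficient_option(self, random_unit_dictionary, rng):
        y = rng.standard_normal(16)
        code = omp1(random_unit_dictionary, y, 3, refit=False)
        corr = random_unit_dictionary.T @ y
        for j in code.support:
            assert code.coefficients[j] == pytest.approx(corr[j])


class TestHardAssign:
    def test_exact_atom_zero_residual(self, random_unit_dictionary):
        code = hard_assign(random_unit_dictionary, random_unit_dictionary[:, 5])
        assert code.support == (5,)
        assert code.coefficients[5] == 1.0
        assert code.residual_norm < 1e-12

    def test_nearest_equals_signed_inner_product_for_unit_atoms(
        self, random_unit_dictionary, rng
    ):
        y = rng.standard_normal(16)
        code = hard_assign(random_unit_dictionary, y)
        assert code.support[0] == int(np.argmax(random_unit_dictionary.T @ y))

    def test_tie_breaks_to_lowest_index(self):
        atom = np.array([1.0, 0.0])
        D = np.stack([atom, atom], axis=1)  # two identical atoms
        code = hard_assign(D, np.array([0.3, 0.4]))
        assert code.support == (0,)


class TestEncodeMatrix:
    @pytest.mark.parametrize("coder,T", [("omp", 3), ("omp1", 3), ("hard", 1)])
    def test_batch_equals_per_row(self, random_unit_dictionary, rng, coder, T):
        X = rng.standard_normal((40, 16))
        codes = encode_matrix(random_unit_dictionary, X, coder=coder, T=T)
        assert len(codes) == 40
        single = {"omp": omp, "omp1": omp1}.get(coder)
        for i, code in enumerate(codes):
            ref = (
                single(random_unit_dictionary, X[i], T)
                if single
                else hard_assign(random_unit_dictionary, X[i])
            )
            assert code.support == ref.support
            np.testing.assert_allclose(code.coefficients, ref.coefficients, atol=1e-10)
            assert code.residual_norm == pytest.approx(ref.residual_norm, abs=1e-9)

    def test_batching_is_pure(self, random_unit_dictionary, rng):
        X = rng.standard_normal((30, 16))
        whole = encode_matrix(random_unit_dictionary, X, "omp", 4)
        halves = encode_matrix(random_unit_dictionary, X[:15], "omp", 4) + encode_matrix(
            random_unit_dictionary, X[15:], "omp", 4
        )
        for a, b in zip(whole, halves):
            assert a.support == b.support
            np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_empty_matrix(self, random_unit_dictionary):
        assert encode_matrix(random_unit_dictionary, np.zeros((0, 16)), "omp", 2) == []

    def test_zero_signal_gets_empty_support(self, random_unit_dictionary):
        codes = encode_matrix(random_unit_dictionary, np.zeros((1, 16)), "omp", 3)
        assert codes[0].support == ()
        assert codes[0].residual_norm == 0.0

    def test_unknown_coder_rejected(self, random_unit_dictionary):
        with pytest.raises(ValueError, match="unknown coder"):
            encode_matrix(random_unit_dictionary, np.zeros((2, 16)), "omp2", 2)


def test_batch_solvers_match_lstsq_to_1e10(rng):
    # normal-equation batch solve vs QR-based lstsq on the same supports
    D = rng.standard_normal((16, 48))
    D /= np.linalg.norm(D, axis=0)
    X = rng.standard_normal((100, 16))
    for fn in (batch_omp, batch_omp1):
        supports, coefs, n_sel, _ = fn(D, X, 4)
        for i in range(0, 100, 17):
            s = supports[i, : n_sel[i]]
            ref, *_ = np.linalg.lstsq(D[:, s], X[i], rcond=None)
            np.testing.assert_allclose(coefs[i, : n_sel[i]], ref, atol=1e-10)
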