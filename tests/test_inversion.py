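import numpy as np
import pytest

import isqsm
from isqsm.dipole import fft3
from isqsm.errors import (
    ConfigurationError,
    ContractError,
    NumericalError,
    ValidationError,
)
from isqsm.supports import KSpaceSupport

from oracles import dense_minimum_norm_solution


def _as_complex(x):
    return np.asarray(x, dtype=complex)


class TestCgls:
    def test_identity_operator_returns_rhs_in_one_iteration(self, rng):
        rhs = _as_complex(rng.standard_normal(12))
        x, history, converged = isqsm.cgls_solve(
            lambda v: _as_complex(v), lambda v: np.asarray(v).real, rhs, tol=1e-10
        )
        assert converged and len(history) == 2
        np.testing.assert_allclose(x, rhs.real, rtol=1e-10)

    def test_diagonal_operator_closed_form(self, rng):
        a = rng.uniform(1.0, 3.0, size=10)
        rhs = _as_complex(rng.standard_normal(10))
        x, _, converged = isqsm.cgls_solve(
            lambda v: _as_complex(a * v),
            lambda v: (a * np.asarray(v)).real,
            rhs,
            tol=1e-12,
            max_iter=100,
        )
        assert converged
        np.testing.assert_allclose(x, rhs.real / a, rtol=1e-8)

    def test_singular_diagonal_gives_minimum_norm_solution(self, rng):
        """Zero start ⇒ zeros along null directions, pseudoinverse elsewhere."""
        a = np.array([2.0, 0.0, 1.0, 0.0, 3.0, 0.5, 0.0, 1.5, 2.5, 0.0])
        rhs = _as_complex(rng.standard_normal(10))
        x, _, _ = isqsm.cgls_solve(
            lambda v: _as_complex(a * v),
            lambda v: (a * np.asarray(v)).real,
            rhs,
            tol=1e-12,
            max_iter=100,
        )
        expected = np.linalg.pinv(np.diag(a)) @ rhs.real
        np.testing.assert_allclose(x, expected, atol=1e-10)

    def test_zero_rhs_returns_zero_without_iterating(self):
        x, history, converged = isqsm.cgls_solve(
            lambda v: _as_complex(v), lambda v: np.asarray(v).real, np.zeros(5, complex)
        )
        assert converged and history == [0.0]
        assert np.all(x == 0)

    def test_non_adjoint_pair_rejected(self, rng):
        rhs = _as_complex(rng.standard_normal(8))
        with pytest.raises(ContractError):
            isqsm.cgls_solve(
                lambda v: 2.0 * _as_complex(v), lambda v: np.asarray(v).real, rhs
            )


class TestComputeNu:
    def test_zero_field_gives_zero_nu(self, grid8):
        kernel = isqsm.dipole_kernel(grid8)
        support = isqsm.band_limit(kernel, 0.25)
        field = isqsm.LocalFieldMap(grid=grid8, values=np.zeros(grid8.shape))
        nu = isqsm.compute_nu(field, kernel, support)
        assert np.all(nu.values == 0)

    def test_round_trip_recovers_chi_spectrum_on_support(self, grid8, rng):
        """ν = D⁻¹·D·Fχ = Fχ on the band limit for a forward-simulated field."""
        kernel = isqsm.dipole_kernel(grid8)
        support = isqsm.band_limit(kernel, 0.25)
        chi = rng.standard_normal(grid8.shape)
        field = isqsm.forward_field(
            isqsm.SusceptibilityMap(grid=grid8, values=chi), kernel
        )
        nu = isqsm.compute_nu(field, kernel, support)
        sel = support.values
        np.testing.assert_allclose(nu.values[sel], fft3(chi)[sel], rtol=1e-8)
        assert np.all(nu.values[~sel] == 0)

    def test_conjugate_symmetry_for_real_field(self, grid8, rng):
        kernel = isqsm.dipole_kernel(grid8)
        support = isqsm.band_limit(kernel, 0.25)
        field = isqsm.LocalFieldMap(grid=grid8, values=rng.standard_normal(grid8.shape))
        nu = isqsm.compute_nu(field, kernel, support).values
        for ax in range(3):
            nu = np.roll(np.flip(nu, axis=ax), 1, axis=ax)
        np.testing.assert_allclose(nu.conj(), isqsm.compute_nu(field, kernel, support).values, atol=1e-10)

    def test_support_touching_kernel_zero_rejected(self, grid8, rng):
        kernel = isqsm.dipole_kernel(grid8)
        values = np.abs(kernel.values) > 0.25
        values[0, 0, 0] = True  # sneak in the k = 0 voxel where D = 0
        bad = KSpaceSupport(grid=grid8, values=values, t_well=0.25)
        field = isqsm.LocalFieldMap(grid=grid8, values=rng.standard_normal(grid8.shape))
        with pytest.raises(NumericalError):
            isqsm.compute_nu(field, kernel, bad)


class TestIsReconstruct:
    def test_zero_field_reconstructs_zero(self, grid8):
        kernel = isqsm.dipole_kernel(grid8)
        mask = isqsm.ImageSupport(grid=grid8, values=np.ones(grid8.shape, np.uint8))
        field = isqsm.LocalFieldMap(grid=grid8, values=np.zeros(grid8.shape))
        res = isqsm.is_reconstruct(field, mask, kernel)
        assert np.all(res.chi.values == 0)
        assert res.iterations <= 1 and res.converged

    def test_empty_mask_rejected(self, grid8):
        kernel = isqsm.dipole_kernel(grid8)
        mask = isqsm.ImageSupport(grid=grid8, values=np.zeros(grid8.shape, np.uint8))
        field = isqsm.LocalFieldMap(grid=grid8, values=np.zeros(grid8.shape))
        with pytest.raises(ConfigurationError):
            isqsm.is_reconstruct(field, mask, kernel)

    def test_empty_band_limit_rejected(self, grid8):
        kernel = isqsm.dipole_kernel(grid8)
        mask = isqsm.ImageSupport(grid=grid8, values=np.ones(grid8.shape, np.uint8))
        field = isqsm.LocalFieldMap(grid=grid8, values=np.zeros(grid8.shape))
        with pytest.raises(ConfigurationError):
            isqsm.is_reconstruct(
                field, mask, kernel, isqsm.SolverConfig(t_well=0.9)
            )

    def test_matches_dense_minimum_norm_oracle(self, grid8, rng):
        """CGLS solution equals the explicit dense LS solve on an 8³ grid."""
        kernel = isqsm.dipole_kernel(grid8)
        mask_arr = (rng.random(grid8.shape) < 0.3).astype(np.uint8)
        mask = isqsm.ImageSupport(grid=grid8, values=mask_arr)
        chi_true = rng.standard_normal(grid8.shape) * mask_arr
        field = isqsm.forward_field(
            isqsm.SusceptibilityMap(grid=grid8, values=chi_true), kernel
        )
        res = isqsm.is_reconstruct(
            field, mask, kernel,
            isqsm.SolverConfig(t_well=0.25, tol=1e-12, max_iter=2000),
        )
        support = isqsm.band_limit(kernel, 0.25)
        masked_field, _ = isqsm.validate_support_consistency(field, mask)
        nu = isqsm.compute_nu(masked_field, kernel, support)
        expected = dense_minimum_norm_solution(
            grid8.shape, mask_arr, support.values, nu.values
        )
        rel = np.linalg.norm(res.chi.values - expected) / np.linalg.norm(expected)
        assert rel < 1e-6

    def test_residual_history_non_increasing(self, is_recon64):
        h = is_recon64.residual_history
        assert all(np.isfinite(h))
        assert all(b <= a for a, b in zip(h, h[1:]))

    def test_solution_vanishes_outside_mask_exactly(self, phantom64, is_recon64):
        outside = phantom64.mask.values == 0
        assert np.all(is_recon64.chi.values[outside] == 0)

    def test_spectrum_infilling_outside_band_limit(self, phantom64, kernel64, is_recon64):
        """The reconstruction fills in the excluded cone with nonzero energy
        while staying consistent with ν on the band limit."""
        support = isqsm.band_limit(kernel64, 0.25)
        spec = fft3(is_recon64.chi.values)
        energy_out = np.abs(spec[~support.values]) ** 2
        assert energy_out.sum() > 0
        masked_field, _ = isqsm.validate_support_consistency(
            phantom64.field, phantom64.mask
        )
        nu = isqsm.compute_nu(masked_field, kernel64, support)
        final_mismatch = np.linalg.norm(spec[support.values] - nu.values[support.values])
        assert final_mismatch == pytest.approx(is_recon64.residual_history[-1], rel=1e-6)


class TestRegularized:
    def test_lambda_zero_matches_plain_least_squares(self, grid8, rng):
        """With an all-ones mask the LS solution is Fᴴ(S_kν) for both solvers."""
        kernel = isqsm.dipole_kernel(grid8)
        mask = isqsm.ImageSupport(grid=grid8, values=np.ones(grid8.shape, np.uint8))
        field = isqsm.LocalFieldMap(grid=grid8, values=rng.standard_normal(grid8.shape))
        cfg = isqsm.SolverConfig(t_well=0.25, lambda_l1=0.0, max_iter=50, tol=1e-12)
        r_prox = isqsm.is_reconstruct_regularized(field, mask, kernel, cfg)
        r_cgls = isqsm.is_reconstruct(field, mask, kernel, cfg)
        np.testing.assert_allclose(r_prox.chi.values, r_cgls.chi.values, atol=1e-8)

    def test_large_lambda_shrinks_to_zero(self, grid8, rng):
        kernel = isqsm.dipole_kernel(grid8)
        mask = isqsm.ImageSupport(grid=grid8, values=np.ones(grid8.shape, np.uint8))
        field = isqsm.LocalFieldMap(grid=grid8, values=rng.standard_normal(grid8.shape))
        cfg = isqsm.SolverConfig(t_well=0.25, lambda_l1=1e4, max_iter=20)
        res = isqsm.is_reconstruct_regularized(field, mask, kernel, cfg)
        assert np.all(res.chi.values == 0)

    def test_objective_history_non_increasing(self, grid8, rng):
        kernel = isqsm.dipole_kernel(grid8)
        mask_arr = (rng.random(grid8.shape) < 0.5).astype(np.uint8)
        mask = isqsm.ImageSupport(grid=grid8, values=mask_arr)
        field = isqsm.LocalFieldMap(
            grid=grid8, values=rng.standard_normal(grid8.shape) * mask_arr
        )
        cfg = isqsm.SolverConfig(t_well=0.25, lambda_l1=1e-3, max_iter=40)
        res = isqsm.is_reconstruct_regularized(field, mask, kernel, cfg)
        h = res.residual_history
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    def test_unknown_wavelet_rejected(self, grid8):
        kernel = isqsm.dipole_kernel(grid8)
        mask = isqsm.ImageSupport(grid=grid8, values=np.ones(grid8.shape, np.uint8))
        field = isqsm.LocalFieldMap(grid=grid8, values=np.zeros(grid8.shape))
        cfg = isqsm.SolverConfig(t_well=0.25, lambda_l1=1e-3, wavelet_name="nosuch")
        with pytest.raises(ValidationError):
            isqsm.is_reconstruct_regularized(field, mask, kernel, cfg)


class TestThresholdSweep:
    def _problem(self, rng, n=12):
        grid = isqsm.VolumeGrid((n, n, n))
        kernel = isqsm.dipole_kernel(grid)
        mask_arr = np.zeros(grid.shape, np.uint8)
        mask_arr[2:-2, 2:-2, 2:-2] = 1
        mask = isqsm.ImageSupport(grid=grid, values=mask_arr)
        chi = rng.standard_normal(grid.shape) * mask_arr * 0.05
        truth = isqsm.SusceptibilityMap(grid=grid, values=chi)
        field = isqsm.forward_field(truth, kernel)
        field = isqsm.LocalFieldMap(grid=grid, values=field.values * mask_arr)
        return field, mask, kernel, truth

    def test_single_threshold_single_row(self, rng):
        field, mask, kernel, truth = self._problem(rng)
        res = isqsm.threshold_sweep(
            field, mask, kernel, truth, [0.25], isqsm.SolverConfig(max_iter=5)
        )
        assert len(res.table) == 1
        assert res.best_xsim["t_well"] == 0.25

    def test_argmax_rows_match_table(self, rng):
        field, mask, kernel, truth = self._problem(rng)
        res = isqsm.threshold_sweep(
            field, mask, kernel, truth, [0.1, 0.2, 0.3], isqsm.SolverConfig(max_iter=5)
        )
        assert len(res.table) == 3
        assert res.best_xsim["xsim"] == res.table["xsim"].max()
        assert res.best_psnr["psnr"] == res.table["psnr"].max()

    @pytest.mark.parametrize("bad", [[], [0.3, 0.1], [-0.1, 0.2]])
    def test_invalid_threshold_lists_rejected(self, rng, bad):
        field, mask, kernel, truth = self._problem(rng)
        with pytest.raises(ValidationError):
            isqsm.threshold_sweep(field, mask, kernel, truth, bad)
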