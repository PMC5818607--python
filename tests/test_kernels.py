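"""Spectral graph machinery: Laplacians, heat kernels, signal evolution."""

import numpy as np
import pytest
from scipy.linalg import expm

from mklconn import (
    DegenerateGraphError,
    GraphSignal,
    ScaleSet,
    StructuralConnectome,
    ValidationError,
    build_kernel_bank,
    build_laplacian,
    default_scale_set,
    diffusion_kernel,
    evolve_graph_signal,
)
from conftest import random_connected_sc


class TestBuildLaplacian:
    def test_two_node_graph_has_normalized_spectrum_zero_two(self, k2_sc):
        spec = build_laplacian(k2_sc)
        assert np.allclose(spec.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_complete_graph_normalized_spectrum(self):
        n = 5
        W = np.ones((n, n)) - np.eye(n)
        sc = StructuralConnectome.from_weights(W)
        spec = build_laplacian(sc)
        expected = np.array([0.0] + [1.25] * 4)
        assert np.allclose(spec.eigenvalues, expected, atol=1e-10)
        # cross-check against a dense eigensolve of the explicit matrix
        L = np.eye(n) - W / 4.0
        assert np.allclose(np.sort(np.linalg.eigvalsh(L)).clip(0),
                           spec.eigenvalues, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_null_space_and_reconstruction(self, seed):
        sc = random_connected_sc(9, seed)
        spec = build_laplacian(sc)
        assert spec.eigenvalues[0] <= 1e-8
        null = np.sqrt(sc.degrees)
        null /= np.linalg.norm(null)
        v0 = spec.eigenvectors[:, 0]
        assert np.allclose(np.abs(v0 @ null), 1.0, atol=1e-8)
        Psi = spec.eigenvectors
        assert np.allclose(Psi.T @ Psi, np.eye(sc.n), atol=1e-8)
        assert np.allclose(Psi @ np.diag(spec.eigenvalues) @ Psi.T,
                           spec.laplacian, atol=1e-8)

    def test_unnormalized_variant_is_degree_minus_weights(self, ring_sc):
        spec = build_laplacian(ring_sc, normalization="unnormalized")
        assert np.allclose(spec.laplacian,
                           np.diag(ring_sc.degrees) - ring_sc.weights)

    def test_isolated_node_raises_degenerate_error(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        sc = StructuralConnectome.from_weights(W, allow_isolated=True)
        with pytest.raises(DegenerateGraphError):
            build_laplacian(sc)

    def test_asymmetric_input_beyond_tolerance_rejected(self):
        W = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            StructuralConnectome.from_weights(W)


class TestDiffusionKernel:
    def test_zero_scale_is_identity(self, small_spec):
        assert np.allclose(diffusion_kernel(small_spec, 0.0),
                           np.eye(small_spec.n), atol=1e-12)

    def test_negative_scale_rejected(self, small_spec):
        with pytest.raises(ValidationError):
            diffusion_kernel(small_spec, -0.1)

    def test_semigroup_property(self, small_spec):
        H1 = diffusion_kernel(small_spec, 0.3)
        H2 = diffusion_kernel(small_spec, 0.7)
        H12 = diffusion_kernel(small_spec, 1.0)
        assert np.allclose(H1 @ H2, H12, atol=1e-8)

    def test_large_scale_converges_to_stationary_projector(self, small_spec):
        H = diffusion_kernel(small_spec, 1e3)
        v0 = small_spec.eigenvectors[:, 0]
        assert np.allclose(H, np.outer(v0, v0), atol=1e-6)

    @pytest.mark.parametrize("n,seed,gamma", [(6, 0, 0.5), (12, 1, 1.7), (20, 2, 0.05)])
    def test_matches_dense_matrix_exponential(self, n, seed, gamma):
        spec = build_laplacian(random_connected_sc(n, seed))
        assert np.allclose(diffusion_kernel(spec, gamma),
                           expm(-gamma * spec.laplacian), atol=1e-8)

    def test_invariant_to_eigenvector_sign_flips(self, small_spec):
        H = diffusion_kernel(small_spec, 0.9)
        flipped = small_spec
        flipped.eigenvectors = flipped.eigenvectors * (-1.0)
        assert np.allclose(diffusion_kernel(flipped, 0.9), H, atol=1e-10)

    def test_symmetric_psd(self, small_spec):
        H = diffusion_kernel(small_spec, 0.4)
        assert np.abs(H - H.T).max() < 1e-10
        assert np.linalg.eigvalsh(H).min() >= -1e-10

    def test_trace_monotone_nonincreasing_in_scale(self, small_spec):
        traces = [np.trace(diffusion_kernel(small_spec, g))
                  for g in np.linspace(0, 5, 20)]
        assert np.all(np.diff(traces) <= 1e-12)


class TestKernelBank:
    def test_single_zero_scale_bank_is_identity(self, small_spec):
        bank = build_kernel_bank(small_spec, ScaleSet([0.0]))
        assert np.allclose(bank.stacked, np.eye(small_spec.n))

    def test_default_bank_has_sixteen_kernels(self, small_spec):
        scale_set = default_scale_set(small_spec)
        bank = build_kernel_bank(small_spec, scale_set)
        n = small_spec.n
        assert scale_set.m == 16
        assert bank.stacked.shape == (n, 16 * n)

    def test_stacked_blocks_equal_individual_kernels(self, small_spec):
        scale_set = ScaleSet([0.1, 0.5, 2.0])
        bank = build_kernel_bank(small_spec, scale_set)
        n = small_spec.n
        for i, g in enumerate(scale_set.scales):
            block = bank.stacked[:, i * n:(i + 1) * n]
            assert np.allclose(block, diffusion_kernel(small_spec, g), atol=1e-12)
            assert np.allclose(block, bank.kernels[i])


class TestDefaultScaleSet:
    def test_scales_strictly_increasing(self, small_spec):
        s = default_scale_set(small_spec).scales
        assert np.all(np.diff(s) > 0)

    def test_endpoints_meet_deviation_targets(self, small_spec):
        s = default_scale_set(small_spec).scales
        n = small_spec.n
        H_min = diffusion_kernel(small_spec, s[0])
        v0 = small_spec.eigenvectors[:, 0]
        H_max = diffusion_kernel(small_spec, s[-1])
        assert np.linalg.norm(H_min - np.eye(n)) == pytest.approx(0.01 * n, rel=1e-6)
        assert np.linalg.norm(H_max - np.outer(v0, v0)) == pytest.approx(
            0.01 * n, rel=1e-6)

    def test_doubling_m_preserves_endpoints(self, small_spec):
        s16 = default_scale_set(small_spec, m=16).scales
        s32 = default_scale_set(small_spec, m=32).scales
        assert s32[0] == pytest.approx(s16[0], rel=1e-12)
        assert s32[-1] == pytest.approx(s16[-1], rel=1e-12)

    def test_disconnected_graph_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        spec = build_laplacian(StructuralConnectome.from_weights(W))
        with pytest.raises(DegenerateGraphError):
            default_scale_set(spec)


class TestEvolveGraphSignal:
    def test_zero_time_returns_initial_signal(self, small_spec):
        u0 = GraphSignal(np.arange(small_spec.n, dtype=float))
        out = evolve_graph_signal(small_spec, u0, t=0.0, tau=1.0, sigma2=0.5)
        assert np.allclose(out.values, u0.values, atol=1e-12)

    def test_null_eigenvector_is_stationary(self, small_spec):
        u0 = GraphSignal(small_spec.eigenvectors[:, 0])
        out = evolve_graph_signal(small_spec, u0, t=50.0, tau=1.0, sigma2=0.5)
        assert np.allclose(out.values, u0.values, atol=1e-10)

    def test_long_time_limit_is_null_mode_projection(self, small_spec):
        rng = np.random.default_rng(5)
        u0 = GraphSignal(rng.standard_normal(small_spec.n))
        out = evolve_graph_signal(small_spec, u0, t=1e4, tau=1.0, sigma2=0.5)
        v0 = small_spec.eigenvectors[:, 0]
        assert np.allclose(out.values, v0 * (v0 @ u0.values), atol=1e-8)

    def test_negative_time_rejected(self, small_spec):
        with pytest.raises(ValidationError):
            evolve_graph_signal(small_spec, GraphSignal(np.zeros(small_spec.n)),
                                t=-1.0, tau=1.0, sigma2=0.5)

    def test_small_variance_matches_first_order_taylor_rates(self, small_spec):
        # exp(-(1 - e^{-lam s2/2}) t/tau) vs exp(-lam s2 t /(2 tau))
        sigma2, tau, t = 1e-3, 1.0, 2.0
        lam = small_spec.eigenvalues
        exact = np.exp(-(1 - np.exp(-lam * sigma2 / 2)) * t / tau)
        taylor = np.exp(-lam * sigma2 * t / (2 * tau))
        bound = 10 * (sigma2 * lam.max() / 2) ** 2
        rel = np.abs(exact - taylor) / taylor
        assert rel.max() <= bound
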