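"""Graph Laplacians, spectral decompositions, and multi-scale diffusion kernels.

The diffusion kernel at scale gamma on a graph with Laplacian
L = Psi Lambda Psi^T is

    H(gamma) = Psi exp(-Lambda gamma) Psi^T,

the heat kernel of the graph: it propagates activity over the connectome,
with small gamma keeping activity local and large gamma spreading it to the
stationary pattern.  The matrix exponential is evaluated spectrally, which
is exact for a symmetric Laplacian.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .types import (
    DegenerateGraphError,
    DiffusionKernelBank,
    GraphSignal,
    ScaleSet,
    SpectralDecomposition,
    StructuralConnectome,
    ValidationError,
)

NORMALIZATIONS = ("symmetric_normalized", "unnormalized")


def build_laplacian(
    sc: StructuralConnectome,
    normalization: str = "symmetric_normalized",
) -> SpectralDecomposition:
    """Construct and diagonalize the graph Laplacian of a structural connectome.

    ``symmetric_normalized`` (default) builds L = I - D^{-1/2} W D^{-1/2};
    ``unnormalized`` builds L = D - W.  Eigenvalues are returned ascending
    with tiny negative round-off clipped to zero; each eigenvector's sign is
    fixed so its largest-magnitude entry is positive.
    """
    if normalization not in NORMALIZATIONS:
        raise ValidationError(f"unknown normalization {normalization!r}")
    W = sc.weights
    d = W.sum(axis=1)
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0))
        raise DegenerateGraphError(f"isolated node {bad} (zero degree)")
    if normalization == "symmetric_normalized":
        inv_sqrt = 1.0 / np.sqrt(d)
        L = np.eye(sc.n) - (inv_sqrt[:, None] * W) * inv_sqrt[None, :]
    else:
        L = np.diag(d) - W
    L = 0.5 * (L + L.T)
    eigenvalues, eigenvectors = np.linalg.eigh(L)
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    # Deterministic sign convention: largest-magnitude entry positive.
    for k in range(eigenvectors.shape[1]):
        v = eigenvectors[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            eigenvectors[:, k] = -v
    return SpectralDecomposition(
        laplacian=L,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        normalization=normalization,
        degrees=d,
    )


def diffusion_kernel(spec: SpectralDecomposition, gamma: float) -> np.ndarray:
    """Evaluate the heat kernel H(gamma) = Psi exp(-Lambda gamma) Psi^T.

    gamma = 0 yields the identity; negative gamma is a domain error.  The
    result is symmetric positive semi-definite by construction.
    """
    if gamma < 0:
        raise ValidationError("diffusion scale gamma must be nonnegative")
    decay = np.exp(-spec.eigenvalues * gamma)
    H = (spec.eigenvectors * decay[None, :]) @ spec.eigenvectors.T
    return 0.5 * (H + H.T)


def build_kernel_bank(
    spec: SpectralDecomposition,
    scale_set: ScaleSet,
    subject_id: str = "",
) -> DiffusionKernelBank:
    """Build all m kernels of one subject plus the stacked form [H_1 ... H_m]."""
    kernels = [diffusion_kernel(spec, g) for g in scale_set.scales]
    return DiffusionKernelBank(
        kernels=kernels,
        stacked=np.hstack(kernels),
        scale_set=scale_set,
        subject_id=subject_id,
    )


def _identity_deviation(eigenvalues: np.ndarray, gamma: float) -> float:
    # ||H(gamma) - I||_F from the spectrum alone.
    return float(np.sqrt(np.sum((np.exp(-eigenvalues * gamma) - 1.0) ** 2)))


def _stationary_deviation(eigenvalues: np.ndarray, gamma: float) -> float:
    # ||H(gamma) - Psi_0 Psi_0^T||_F; the null mode contributes nothing.
    nz = eigenvalues[eigenvalues > 1e-12]
    return float(np.sqrt(np.sum(np.exp(-2.0 * nz * gamma))))


def default_scale_set(spec: SpectralDecomposition, m: int = 16) -> ScaleSet:
    """Data-driven log-spaced scale set.

    The endpoints are found by bisection on gamma: gamma_min is the smallest
    scale whose kernel deviates from the identity by Frobenius norm 0.01*n
    (smaller scales are indistinguishable from no diffusion) and gamma_max is
    the scale whose kernel is within 0.01*n of the rank-1 stationary projector
    (larger scales add nothing).  m scales are log-spaced between them; the
    endpoints are independent of m, so refining m nests the previous grids.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not spec.is_connected():
        raise DegenerateGraphError(
            "disconnected graph: stationary projector undefined")
    n = spec.n
    ev = spec.eigenvalues
    target = 0.01 * n
    lo, hi = 1e-12, 1.0
    while _identity_deviation(ev, hi) < target:
        hi *= 2.0
        if hi > 1e12:
            raise DegenerateGraphError("identity-deviation target unreachable")
    gamma_min = brentq(lambda g: _identity_deviation(ev, g) - target, lo, hi,
                       xtol=1e-12, rtol=1e-12)
    lo, hi = gamma_min, max(2.0 * gamma_min, 1.0)
    while _stationary_deviation(ev, hi) > target:
        hi *= 2.0
        if hi > 1e15:
            raise DegenerateGraphError("stationary-deviation target unreachable")
    gamma_max = brentq(lambda g: _stationary_deviation(ev, g) - target, lo, hi,
                       xtol=1e-12, rtol=1e-12)
    if m == 1:
        return ScaleSet(np.array([gamma_min]))
    return ScaleSet(np.geomspace(gamma_min, gamma_max, m))


def evolve_graph_signal(
    spec: SpectralDecomposition,
    u0: GraphSignal,
    t: float,
    tau: float,
    sigma2: float,
) -> GraphSignal:
    """Evolve a graph signal under the linearized reaction-diffusion flow.

    Between reaction instances the regional activity u obeys
    tau du/dt = -u + Psi exp(-Lambda sigma^2/2) Psi^T u, whose solution is

        u(t) = Psi exp(-(1/tau)(I - exp(-Lambda sigma^2/2)) t) Psi^T u0.

    The Laplacian null mode never decays; every other mode relaxes at a rate
    set by its harmonic's spatial frequency.
    """
    if t < 0:
        raise ValidationError("evolution time must be nonnegative")
    if tau <= 0 or sigma2 <= 0:
        raise ValidationError("tau and sigma2 must be positive")
    u = np.asarray(u0.values, dtype=float)
    if u.shape != (spec.n,):
        raise ValidationError(f"signal length {u.shape} != n={spec.n}")
    rates = (1.0 - np.exp(-spec.eigenvalues * sigma2 / 2.0)) / tau
    beta = spec.eigenvectors.T @ u
    beta = np.exp(-rates * t) * beta
    return GraphSignal(values=spec.eigenvectors @ beta, time=t)
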