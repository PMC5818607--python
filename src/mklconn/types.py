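"""Core data containers for connectome modelling.

The containers mirror the objects of the multi-scale diffusion model:
structural connectomes (weighted brain graphs), their Laplacian spectra,
banks of diffusion kernels H(gamma) = Psi exp(-Lambda gamma) Psi^T,
functional connectomes (correlation matrices), and the learned stack of
scale-specific co-activation matrices pi_1..pi_m.

All matrices are plain numpy arrays; construction classmethods perform
validation so that downstream numerical code can assume the invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


class ValidationError(ValueError):
    """An input violates a structural invariant (shape, symmetry, range)."""


class DegenerateGraphError(ValueError):
    """The graph cannot support the requested spectral operation
    (isolated node, disconnected graph, ...)."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero-variance input)."""


class IntegrationError(RuntimeError):
    """A stochastic integration produced a non-finite state."""


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(f"{name} has non-finite entry at ({i}, {j})")
    return arr


@dataclass
class StructuralConnectome:
    """A subject's structural connectivity graph.

    ``weights`` is the symmetric nonnegative weighted adjacency matrix W
    (zero diagonal).  ``isolated_nodes`` is populated by operations (e.g.
    thresholding) that may disconnect regions; a freshly validated
    connectome has none.
    """

    weights: np.ndarray
    region_labels: list[str]
    subject_id: str = ""
    isolated_nodes: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @classmethod
    def from_weights(
        cls,
        weights,
        region_labels: Sequence[str] | None = None,
        subject_id: str = "",
        allow_isolated: bool = False,
    ) -> "StructuralConnectome":
        """Sanitize and validate a raw weight matrix.

        Tractography matrices are near- but not exactly symmetric, so the
        matrix is symmetrized as (W + W^T)/2 and its diagonal zeroed before
        validation.  Asymmetry beyond a relative tolerance of 1e-6, negative
        weights, or (unless ``allow_isolated``) a zero-degree node raise
        :class:`ValidationError`.
        """
        W = _as_float_matrix(weights, "SC weights")
        scale = np.abs(W).max() if W.size else 1.0
        if scale > 0 and np.abs(W - W.T).max() > 1e-6 * scale:
            raise ValidationError("SC weights asymmetric beyond tolerance")
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        if W.min() < 0:
            i, j = np.argwhere(W < 0)[0]
            raise ValidationError(f"negative SC weight at ({i}, {j})")
        isolated = tuple(int(i) for i in np.flatnonzero(W.sum(axis=1) <= 0))
        if isolated and not allow_isolated:
            raise ValidationError(f"isolated node(s) {isolated} in SC")
        n = W.shape[0]
        labels = list(region_labels) if region_labels is not None else [f"R{i}" for i in range(n)]
        if len(labels) != n:
            raise ValidationError(f"{len(labels)} region labels for {n} nodes")
        return cls(weights=W, region_labels=labels, subject_id=subject_id,
                   isolated_nodes=isolated)


@dataclass
class SpectralDecomposition:
    """Eigen-decomposition of a graph Laplacian.

    Columns of ``eigenvectors`` (Psi) are orthonormal and ordered by
    ascending ``eigenvalues`` (diag of Lambda); each eigenvector's sign is
    fixed so its largest-magnitude entry is positive, which makes the
    decomposition reproducible while leaving every kernel H(gamma) =
    Psi exp(-Lambda gamma) Psi^T invariant.
    """

    laplacian: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    normalization: str = "symmetric_normalized"
    degrees: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.laplacian.shape[0]

    def is_connected(self, tol: float = 1e-8) -> bool:
        """A connected graph has a simple zero eigenvalue."""
        return self.n == 1 or self.eigenvalues[1] > tol


@dataclass
class ScaleSet:
    """Strictly increasing diffusion scales gamma_1 < ... < gamma_m.

    gamma = 0 is admitted as the identity kernel.
    """

    scales: np.ndarray

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.scales, dtype=float))
        if s.ndim != 1 or s.size < 1:
            raise ValidationError("scale set must be a non-empty 1-D sequence")
        if np.any(s < 0):
            raise ValidationError("diffusion scales must be nonnegative")
        if s.size > 1 and np.any(np.diff(s) <= 0):
            raise ValidationError("diffusion scales must be strictly increasing")
        self.scales = s

    @property
    def m(self) -> int:
        return self.scales.size

    def __eq__(self, other) -> bool:
        return isinstance(other, ScaleSet) and np.array_equal(self.scales, other.scales)

    def allclose(self, other: "ScaleSet", rtol: float = 1e-10) -> bool:
        return self.m == other.m and np.allclose(self.scales, other.scales, rtol=rtol)


@dataclass
class DiffusionKernelBank:
    """The m diffusion kernels H_i of one subject, plus the horizontally
    stacked form H = [H_1 ... H_m] (n x mn) used as the design block."""

    kernels: list[np.ndarray]
    stacked: np.ndarray
    scale_set: ScaleSet
    subject_id: str = ""

    @property
    def n(self) -> int:
        return self.kernels[0].shape[0]

    @property
    def m(self) -> int:
        return len(self.kernels)


@dataclass
class GraphSignal:
    """A scalar signal on the graph's nodes at one model time."""

    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValidationError("graph signal must be a vector")
        if self.time < 0:
            raise ValidationError("graph signal time must be nonnegative")


@dataclass
class FunctionalConnectome:
    """A subject's functional connectivity: symmetric correlation matrix
    with unit diagonal and entries in [-1, 1]."""

    values: np.ndarray
    subject_id: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_values(cls, values, subject_id: str = "") -> "FunctionalConnectome":
        V = _as_float_matrix(values, "FC values")
        if np.abs(V - V.T).max() > 1e-10:
            raise ValidationError("FC matrix asymmetric beyond 1e-10")
        V = 0.5 * (V + V.T)
        over = np.argwhere(np.abs(V) > 1.0 + 1e-6)
        if over.size:
            i, j = over[0]
            raise ValidationError(
                f"FC entry {V[i, j]:.6g} at ({i}, {j}) outside [-1, 1]")
        V = np.clip(V, -1.0, 1.0)
        if np.abs(np.diag(V) - 1.0).max() > 1e-10:
            i = int(np.argmax(np.abs(np.diag(V) - 1.0)))
            raise ValidationError(f"FC diagonal entry at ({i}, {i}) is not 1")
        np.fill_diagonal(V, 1.0)
        return cls(values=V, subject_id=subject_id)


@dataclass
class PredictedFC:
    """Model-predicted functional connectivity C_f = sum_i H_i pi_i."""

    values: np.ndarray
    symmetrized: bool = True

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CoactivationStack:
    """The learned scale-specific co-activation matrices.

    ``pis`` holds pi_1..pi_m (each n x n, ordered by scale); ``stacked``
    is the vertical stack Pi (mn x n) whose column j is the LASSO variable
    Pi^j.  These are the multi-kernel model's only trained parameters.
    """

    pis: list[np.ndarray]
    stacked: np.ndarray
    scale_set: ScaleSet
    lam: float = 0.0

    @property
    def n(self) -> int:
        return self.stacked.shape[1]

    @property
    def m(self) -> int:
        return len(self.pis)

    @property
    def sparsity(self) -> float:
        """Fraction of exactly-zero entries in Pi."""
        return float(np.mean(self.stacked == 0.0))

    @classmethod
    def from_stacked(cls, stacked: np.ndarray, scale_set: ScaleSet,
                     lam: float = 0.0) -> "CoactivationStack":
        stacked = np.asarray(stacked, dtype=float)
        m = scale_set.m
        if stacked.ndim != 2 or stacked.shape[0] % m != 0:
            raise ValidationError(
                f"stacked Pi shape {stacked.shape} incompatible with m={m}")
        n = stacked.shape[0] // m
        if stacked.shape[1] != n:
            raise ValidationError(
                f"stacked Pi must be (mn x n); got {stacked.shape} with m={m}")
        pis = [stacked[i * n:(i + 1) * n].copy() for i in range(m)]
        return cls(pis=pis, stacked=stacked, scale_set=scale_set, lam=lam)


@dataclass
class TrainingCohort:
    """Aligned (kernel bank, empirical FC) pairs for the p training subjects."""

    subjects: list[tuple[DiffusionKernelBank, FunctionalConnectome]]

    def __post_init__(self):
        if not self.subjects:
            raise ValidationError("training cohort is empty")
        bank0, fc0 = self.subjects[0]
        for bank, fc in self.subjects:
            if bank.n != bank0.n or fc.n != bank0.n:
                raise ValidationError("inconsistent region count across cohort")
            if not bank.scale_set.allclose(bank0.scale_set):
                raise ValidationError("inconsistent scale sets across cohort")

    @property
    def p(self) -> int:
        return len(self.subjects)

    @property
    def n(self) -> int:
        return self.subjects[0][0].n

    @property
    def m(self) -> int:
        return self.subjects[0][0].m

    @property
    def scale_set(self) -> ScaleSet:
        return self.subjects[0][0].scale_set


@dataclass
class Subject:
    """Convenience bundle of all per-subject artifacts used by the
    evaluation protocols."""

    subject_id: str
    sc: StructuralConnectome
    spec: SpectralDecomposition
    bank: DiffusionKernelBank
    fc: FunctionalConnectome


@dataclass
class SDKModel:
    """Single-diffusion-kernel baseline: one cohort-level optimal scale."""

    optimal_scale: float
    scale_grid: np.ndarray
    per_subject_best: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class DMFParameters:
    """Constants of the reduced dynamic-mean-field model.

    Local-population constants follow the reduced-model standards of the
    mean-field lineage; sigma_noise = 0.001 nA and the G range [0, 3] are
    the whole-brain fitting conventions.  All are overridable.

    a: transfer-function gain (nC^-1); b: threshold current offset (Hz);
    d: transfer-function shape (s); gamma_kinetic: kinetic rate; tau_S:
    synaptic gating time constant (s); w: local recurrent weight; J_N:
    synaptic coupling (nA); I_0: external input (nA); G: global coupling;
    sigma_noise: noise amplitude (nA).
    """

    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma_kinetic: float = 0.641
    tau_S: float = 0.1
    w: float = 0.9
    J_N: float = 0.2609
    I_0: float = 0.3
    G: float = 0.0
    sigma_noise: float = 0.001

    def __post_init__(self):
        if self.tau_S <= 0 or self.d <= 0:
            raise ValidationError("tau_S and d must be positive")
        if self.sigma_noise < 0 or self.G < 0:
            raise ValidationError("sigma_noise and G must be nonnegative")


@dataclass
class SimulationSettings:
    """Integration settings for the mean-field + haemodynamic simulation.

    Times are in seconds. ``tr`` is the BOLD sampling interval (2 s mirrors
    typical fMRI repetition times); ``burn_in`` is discarded before sampling.
    """

    dt: float = 1e-3
    duration: float = 500.0
    tr: float = 2.0
    burn_in: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.duration <= self.burn_in:
            raise ValidationError("duration must exceed burn_in")
        if self.tr < self.dt:
            raise ValidationError("tr must be >= dt")


@dataclass
class BOLDTimeseries:
    """Simulated BOLD signal, T samples x n regions, at interval ``tr``."""

    samples: np.ndarray
    tr: float

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n(self) -> int:
        return self.samples.shape[1]


@dataclass
class EvaluationReport:
    """Per-subject and summary prediction scores for one protocol."""

    per_subject: dict[str, float]
    mean_correlation: float
    std_correlation: float
    protocol: str
    folds: dict[str, int] | None = None
    seed: int | None = None

    @classmethod
    def from_scores(cls, per_subject: dict[str, float], protocol: str,
                    folds: dict[str, int] | None = None,
                    seed: int | None = None) -> "EvaluationReport":
        vals = np.array(list(per_subject.values()), dtype=float)
        return cls(per_subject=dict(per_subject),
                   mean_correlation=float(vals.mean()),
                   std_correlation=float(vals.std()),
                   protocol=protocol, folds=folds, seed=seed)


ModelFactory = Callable[[list[Subject]], Callable[[Subject], PredictedFC]]
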