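"""Synthetic SC-FC cohorts with known ground truth.

Real SC-FC cohorts are rarely shareable, so every pipeline stage here is
exercised on generated data: modular weighted graphs stand in for
tractography-derived structural connectomes (heavy-tailed lognormal
weights, denser and stronger within modules, per-subject multiplicative
jitter around a shared group template), and functional connectomes are
produced by the forward model itself, FC = sym(sum_i H_i pi_i) + noise,
from a known sparse co-activation stack.  Because the generating Pi is
known, recovery, support, and robustness claims can all be checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .kernels import build_kernel_bank, build_laplacian, default_scale_set
from .types import (
    CoactivationStack,
    DiffusionKernelBank,
    FunctionalConnectome,
    ScaleSet,
    StructuralConnectome,
    Subject,
    ValidationError,
)

_MAX_REDRAWS = 50


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    n regions, p subjects, m diffusion scales; the SC template has
    ``module_count`` communities with lognormal edge weights
    (location/scale per block type) and block edge densities; each subject
    multiplies template weights by exp(jitter * N(0,1)).  The ground-truth
    Pi has a ``pi_sparsity`` fraction of nonzero entries; generated FCs
    get additive Gaussian noise of sd ``fc_noise_sd`` before rescaling.
    """

    n: int = 20
    p: int = 10
    m: int = 4
    module_count: int = 4
    intra_weight_mu: float = 0.0
    intra_weight_sigma: float = 0.5
    inter_weight_mu: float = -1.5
    inter_weight_sigma: float = 0.5
    intra_density: float = 0.85
    inter_density: float = 0.25
    subject_jitter: float = 0.1
    pi_sparsity: float = 0.05
    fc_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.pi_sparsity <= 1):
            raise ValidationError("pi_sparsity must be in (0, 1]")
        for name in ("n", "p", "m", "module_count"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.module_count > self.n:
            raise ValidationError("more modules than regions")


def _substreams(seed: int, count: int = 4) -> list[np.random.Generator]:
    """Named substreams (template, jitter, pi, fc-noise) from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def _draw_template(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n
    modules = np.arange(n) % spec.module_count
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    same = modules[iu[0]] == modules[iu[1]]
    density = np.where(same, spec.intra_density, spec.inter_density)
    present = rng.random(iu[0].size) < density
    mu = np.where(same, spec.intra_weight_mu, spec.inter_weight_mu)
    sigma = np.where(same, spec.intra_weight_sigma, spec.inter_weight_sigma)
    w = np.exp(mu + sigma * rng.standard_normal(iu[0].size)) * present
    W[iu] = w
    return W + W.T


def _is_connected(W: np.ndarray) -> bool:
    n_comp, _ = connected_components(W > 0, directed=False)
    return n_comp == 1


def generate_sc_cohort(spec: SyntheticCohortSpec) -> list[StructuralConnectome]:
    """Draw the group template (redrawn until connected, bounded retries)
    and the p jittered subject SCs sharing its support."""
    rng_template, rng_jitter, _, _ = _substreams(spec.seed)
    template = None
    for _ in range(_MAX_REDRAWS):
        cand = _draw_template(spec, rng_template)
        if _is_connected(cand):
            template = cand
            break
    if template is None:
        raise ValidationError(
            f"no connected SC template in {_MAX_REDRAWS} draws; "
            "increase densities")
    subjects = []
    n = spec.n
    iu = np.triu_indices(n, k=1)
    for s in range(spec.p):
        noise = np.zeros((n, n))
        noise[iu] = spec.subject_jitter * rng_jitter.standard_normal(iu[0].size)
        noise = noise + noise.T
        W = template * np.exp(noise)
        subjects.append(StructuralConnectome.from_weights(
            W, subject_id=f"sub-{s:03d}"))
    return subjects


def generate_ground_truth_pi(
    spec: SyntheticCohortSpec, scale_set: ScaleSet
) -> CoactivationStack:
    """Sparse random ground-truth Pi: Bernoulli(pi_sparsity) support with
    standard-normal values (symmetric about zero); deterministic under
    the cohort seed."""
    _, _, rng_pi, _ = _substreams(spec.seed)
    mn, n = scale_set.m * spec.n, spec.n
    mask = rng_pi.random((mn, n)) < spec.pi_sparsity
    values = rng_pi.standard_normal((mn, n))
    return CoactivationStack.from_stacked(values * mask, scale_set, lam=0.0)


def generate_fc_cohort(
    banks: list[DiffusionKernelBank],
    stack: CoactivationStack,
    fc_noise_sd: float,
    seed: int,
) -> tuple[list[FunctionalConnectome], list[np.ndarray]]:
    """Forward-generate FCs: FC^s = sym(H^s Pi) + noise, cohort-rescaled.

    Noise is drawn on the upper triangle and mirrored (exactly symmetric).
    A single cohort-level max-abs off-diagonal scalar maps all matrices
    into [-1, 1]; a per-subject scalar would break the shared-Pi linear
    structure that recovery experiments rely on.  Returns the FCs and the
    pre-noise matrices (same scalar applied) for oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    n = stack.n
    iu = np.triu_indices(n, k=1)
    raw, noisy = [], []
    for bank in banks:
        C = bank.stacked @ stack.stacked
        C = 0.5 * (C + C.T)
        raw.append(C)
        E = np.zeros((n, n))
        if fc_noise_sd > 0:
            E[iu] = fc_noise_sd * rng.standard_normal(iu[0].size)
            E = E + E.T
        noisy.append(C + E)
    off_max = max(np.abs(M[iu]).max() for M in noisy)
    scale = off_max if off_max > 0 else 1.0
    fcs, pre_noise = [], []
    for bank, C, M in zip(banks, raw, noisy):
        V = M / scale
        np.fill_diagonal(V, 1.0)
        fcs.append(FunctionalConnectome.from_values(V, subject_id=bank.subject_id))
        pre_noise.append(C / scale)
    return fcs, pre_noise


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[Subject], CoactivationStack, list[np.ndarray]]:
    """Full pipeline: SCs -> spectra -> shared scale set -> banks ->
    ground-truth Pi -> forward FCs.

    The scale set is derived from the first subject's spectrum (subjects
    share a template, so their endpoint scales are nearly identical; the
    model requires one shared scale set).  Returns the subject bundles,
    the generating Pi, and the pre-noise FC matrices.
    """
    scs = generate_sc_cohort(spec)
    specs = [build_laplacian(sc) for sc in scs]
    scale_set = default_scale_set(specs[0], m=spec.m)
    banks = [build_kernel_bank(sp, scale_set, subject_id=sc.subject_id)
             for sp, sc in zip(specs, scs)]
    stack = generate_ground_truth_pi(spec, scale_set)
    _, _, _, rng_fc_seedsrc = _substreams(spec.seed)
    fc_seed = int(rng_fc_seedsrc.integers(2**31))
    fcs, pre_noise = generate_fc_cohort(banks, stack, spec.fc_noise_sd, fc_seed)
    subjects = [
        Subject(subject_id=sc.subject_id, sc=sc, spec=sp, bank=bank, fc=fc)
        for sc, sp, bank, fc in zip(scs, specs, banks, fcs)
    ]
    return subjects, stack, pre_noise


def generate_single_scale_cohort(
    spec: SyntheticCohortSpec, gamma: float
) -> list[Subject]:
    """Cohort whose FC is exactly the kernel at one scale (identity pi).

    This is the single-kernel baseline's own generative model; a scale
    sweep on such a cohort must recover ``gamma`` exactly when it lies on
    the grid.
    """
    scs = generate_sc_cohort(spec)
    iu = None
    subjects = []
    for sc in scs:
        sp = build_laplacian(sc)
        scale_set = ScaleSet(np.array([gamma]))
        bank = build_kernel_bank(sp, scale_set, subject_id=sc.subject_id)
        H = bank.kernels[0]
        if iu is None:
            iu = np.triu_indices(sc.n, k=1)
        V = H / max(np.abs(H[iu]).max(), 1e-12)
        np.fill_diagonal(V, 1.0)
        fc = FunctionalConnectome.from_values(V, subject_id=sc.subject_id)
        subjects.append(Subject(subject_id=sc.subject_id, sc=sc, spec=sp,
                                bank=bank, fc=fc))
    return subjects
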