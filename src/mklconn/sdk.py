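"""Single-diffusion-kernel (SDK) baseline.

The SDK model hypothesizes that one diffusion kernel at one optimal scale
is itself the functional connectivity: the kernel acts on an identity
co-activation, so the spread of activity from each single source region
stands in for its statistical dependence with every other region.  The
scale is chosen per subject by sweeping a grid and keeping the scale whose
kernel best correlates with that subject's empirical FC; the cohort-level
optimum is the mode of the per-subject optima.
"""

from __future__ import annotations

import numpy as np

from .evaluate import fc_correlation
from .kernels import default_scale_set, diffusion_kernel
from .types import (
    FunctionalConnectome,
    PredictedFC,
    SDKModel,
    SpectralDecomposition,
    ValidationError,
)


def default_sdk_grid(spec: SpectralDecomposition, num: int = 50) -> np.ndarray:
    """50 log-spaced scales spanning the default kernel-bank endpoints."""
    endpoints = default_scale_set(spec, m=2).scales
    return np.geomspace(endpoints[0], endpoints[-1], num)


def sdk_scale_sweep(
    spec: SpectralDecomposition,
    fc: FunctionalConnectome,
    scale_grid: np.ndarray,
) -> tuple[float, float]:
    """Sweep the grid; return (best scale, correlation at that scale).

    Correlation is Pearson over off-diagonal entries of H(gamma) vs the
    empirical FC.  Ties break toward the smaller scale.
    """
    grid = np.atleast_1d(np.asarray(scale_grid, dtype=float))
    if grid.size == 0:
        raise ValidationError("scale grid is empty")
    corrs = np.array([
        fc_correlation(PredictedFC(diffusion_kernel(spec, g)), fc)
        for g in grid
    ])
    best = int(np.argmax(corrs))  # first max = smallest scale on sorted grids
    return float(grid[best]), float(corrs[best])


def sdk_fit_cohort(
    cohort: list[tuple[SpectralDecomposition, FunctionalConnectome]],
    scale_grid: np.ndarray,
) -> SDKModel:
    """Fit the cohort-level scale as the mode of per-subject best scales.

    The mode is taken over the grid points themselves (every sweep shares
    the grid); ties break toward the smaller scale.
    """
    grid = np.atleast_1d(np.asarray(scale_grid, dtype=float))
    if not cohort:
        raise ValidationError("SDK cohort is empty")
    per_subject: dict[str, tuple[float, float]] = {}
    counts = np.zeros(grid.size, dtype=int)
    for idx, (spec, fc) in enumerate(cohort):
        best_scale, best_corr = sdk_scale_sweep(spec, fc, grid)
        sid = fc.subject_id or f"subject{idx}"
        per_subject[sid] = (best_scale, best_corr)
        counts[int(np.argmin(np.abs(grid - best_scale)))] += 1
    optimal = float(grid[int(np.argmax(counts))])
    return SDKModel(optimal_scale=optimal, scale_grid=grid,
                    per_subject_best=per_subject)


def sdk_predict(spec: SpectralDecomposition, model: SDKModel) -> PredictedFC:
    """Predict FC as the diffusion kernel at the fitted optimal scale."""
    return PredictedFC(values=diffusion_kernel(spec, model.optimal_scale),
                       symmetrized=True)
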