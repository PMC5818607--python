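"""Reduced dynamic-mean-field (DMF) whole-brain simulator.

Each region i carries a synaptic gating variable S_i driven by a
transfer-function nonlinearity and coupled through the structural
connectome:

    dS_i/dt = -S_i/tau_S + (1 - S_i) * gamma * H(x_i) + sigma * nu_i(t)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
    x_i     = w J_N S_i + G J_N sum_j C_ij S_j + I_0

with nu_i uncorrelated standard Gaussian noise.  Integration is
Euler-Maruyama; the gating trajectory feeds a Balloon-Windkessel
haemodynamic model producing BOLD, which is down-sampled at the scanner
repetition time and correlated to give the simulated FC.  The single free
whole-brain parameter is the global coupling G, fitted per subject by grid
search against empirical FC and summarized over a cohort by the mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import fc_correlation
from .types import (
    BOLDTimeseries,
    DMFParameters,
    FunctionalConnectome,
    IntegrationError,
    PredictedFC,
    SimulationSettings,
    StructuralConnectome,
    ValidationError,
)


@dataclass
class HemodynamicConstants:
    """Balloon-Windkessel constants (Friston-lineage standards).

    kappa: signal decay rate (1/s); gamma_h: flow-dependent elimination
    (1/s); tau_h: haemodynamic transit time (s); alpha: Grubb's vessel
    stiffness exponent; rho: resting oxygen extraction fraction; V0:
    resting venous blood volume fraction.
    """

    kappa: float = 0.65
    gamma_h: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    V0: float = 0.02


def firing_rate(x, params: DMFParameters) -> np.ndarray:
    """Population transfer function H(x) = (ax - b)/(1 - exp(-d(ax - b))).

    The singularity at a x = b is removable: the limit is 1/d.
    """
    x = np.asarray(x, dtype=float)
    u = params.a * x - params.b
    denom = -np.expm1(-params.d * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom != 0, u / np.where(denom != 0, denom, 1.0), 1.0 / params.d)
    return r


def _coupling_matrix(sc: StructuralConnectome, normalize_sc: bool) -> np.ndarray:
    C = sc.weights
    if normalize_sc and C.max() > 0:
        C = C / C.max()
    return C


def dmf_integrate(
    sc: StructuralConnectome,
    params: DMFParameters,
    settings: SimulationSettings,
    normalize_sc: bool = True,
    s0: float = 0.1,
) -> np.ndarray:
    """Euler-Maruyama integration of the gating equations.

    Noise enters as sigma * sqrt(dt) * N(0,1) per node per step; S is
    clipped to [0, 1] after every step (gating is a fraction of open
    channels).  By default the SC is normalized by its maximum entry so
    that G spans a comparable range across cohorts.  Returns the trajectory
    at dt resolution, shape (steps, n).
    """
    C = _coupling_matrix(sc, normalize_sc)
    n = sc.n
    dt = settings.dt
    steps = int(round(settings.duration / dt))
    rng = np.random.default_rng(settings.seed)
    S = np.full(n, s0)
    wJ = params.w * params.J_N
    GJ = params.G * params.J_N
    sqrt_dt = np.sqrt(dt)
    out = np.empty((steps, n))
    check_every = 1000
    for step in range(steps):
        x = wJ * S + GJ * (C @ S) + params.I_0
        r = firing_rate(x, params)
        drift = -S / params.tau_S + (1.0 - S) * params.gamma_kinetic * r
        if params.sigma_noise > 0:
            S = S + dt * drift + params.sigma_noise * sqrt_dt * rng.standard_normal(n)
        else:
            S = S + dt * drift
        np.clip(S, 0.0, 1.0, out=S)
        out[step] = S
        if step % check_every == 0 and not np.all(np.isfinite(S)):
            node = int(np.argmax(~np.isfinite(S)))
            raise IntegrationError(f"non-finite gating at step {step}, node {node}")
    if not np.all(np.isfinite(out)):
        step, node = np.argwhere(~np.isfinite(out))[0]
        raise IntegrationError(f"non-finite gating at step {step}, node {node}")
    return out


def bold_forward(
    S: np.ndarray,
    settings: SimulationSettings,
    hemo: HemodynamicConstants | None = None,
) -> BOLDTimeseries:
    """Balloon-Windkessel transform of a gating trajectory into BOLD.

    Per region, the vasodilatory signal s, inflow f, venous volume v, and
    deoxyhaemoglobin q evolve as

        ds/dt = z - kappa s - gamma_h (f - 1)
        df/dt = s
        dv/dt = (f - v^{1/alpha}) / tau_h
        dq/dt = (f E(f)/rho - v^{1/alpha} q / v) / tau_h,
        E(f)  = 1 - (1 - rho)^{1/f},

    driven by the neural input z = S, integrated at dt.  The BOLD readout
    is V0 (k1 (1-q) + k2 (1 - q/v) + k3 (1 - v)) with k1 = 7 rho, k2 = 2,
    k3 = 2 rho - 0.2.  The burn-in window is discarded and the signal is
    sampled every ``tr`` seconds.
    """
    hemo = hemo or HemodynamicConstants()
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValidationError("gating trajectory must be (steps, n)")
    if not np.all(np.isfinite(S)):
        raise ValidationError("gating trajectory has non-finite values")
    steps, n = S.shape
    dt = settings.dt
    n_keep = int(np.floor((settings.duration - settings.burn_in) / settings.tr))
    if n_keep < 1:
        raise ValidationError("post-burn-in window shorter than one tr")
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    k1 = 7.0 * hemo.rho
    k2 = 2.0
    k3 = 2.0 * hemo.rho - 0.2
    inv_alpha = 1.0 / hemo.alpha
    bold = np.empty((steps, n))
    for step in range(steps):
        z = S[step]
        E = 1.0 - (1.0 - hemo.rho) ** (1.0 / f)
        v_pow = v ** inv_alpha
        ds = z - hemo.kappa * s - hemo.gamma_h * (f - 1.0)
        df = s
        dv = (f - v_pow) / hemo.tau_h
        dq = (f * E / hemo.rho - v_pow * q / v) / hemo.tau_h
        s = s + dt * ds
        f = np.maximum(f + dt * df, 1e-6)
        v = np.maximum(v + dt * dv, 1e-6)
        q = np.maximum(q + dt * dq, 1e-6)
        bold[step] = hemo.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    start = int(round(settings.burn_in / dt))
    stride = int(round(settings.tr / dt))
    samples = bold[start::stride][:n_keep]
    return BOLDTimeseries(samples=samples, tr=settings.tr)


def dmf_fc(bold: BOLDTimeseries) -> FunctionalConnectome:
    """Simulated FC: Pearson correlation matrix of the regional BOLD series."""
    X = bold.samples
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError(
            f"constant BOLD series in region(s) {np.flatnonzero(sd == 0).tolist()}")
    V = np.corrcoef(X.T)
    V = np.clip(0.5 * (V + V.T), -1.0, 1.0)
    np.fill_diagonal(V, 1.0)
    return FunctionalConnectome(values=V)


def simulate_fc(
    sc: StructuralConnectome,
    params: DMFParameters,
    settings: SimulationSettings,
    normalize_sc: bool = True,
) -> FunctionalConnectome:
    """Convenience pipeline: integrate gating, form BOLD, correlate."""
    S = dmf_integrate(sc, params, settings, normalize_sc=normalize_sc)
    return dmf_fc(bold_forward(S, settings))


def dmf_fit_G(
    sc: StructuralConnectome,
    empirical_fc: FunctionalConnectome,
    params: DMFParameters,
    settings: SimulationSettings,
    g_grid: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Grid-search the global coupling G for one subject.

    Every candidate G re-runs the simulation with the same seed (a shared
    noise stream makes candidates comparable).  Returns (best G, its
    correlation, all correlations); ties break toward the smaller G.
    """
    grid = np.atleast_1d(np.asarray(g_grid, dtype=float))
    if grid.size == 0:
        raise ValidationError("G grid is empty")
    corrs = np.empty(grid.size)
    for k, G in enumerate(grid):
        p = DMFParameters(**{**params.__dict__, "G": float(G)})
        fc_sim = simulate_fc(sc, p, settings)
        corrs[k] = fc_correlation(PredictedFC(fc_sim.values), empirical_fc)
    best = int(np.argmax(corrs))
    return float(grid[best]), float(corrs[best]), corrs


def dmf_fit_cohort(
    cohort: list[tuple[StructuralConnectome, FunctionalConnectome]],
    params: DMFParameters,
    settings: SimulationSettings,
    g_grid: np.ndarray,
) -> tuple[float, dict[str, tuple[float, float]]]:
    """Cohort-level G: mode of per-subject optima (ties toward smaller G)."""
    grid = np.atleast_1d(np.asarray(g_grid, dtype=float))
    counts = np.zeros(grid.size, dtype=int)
    per_subject: dict[str, tuple[float, float]] = {}
    for idx, (sc, fc) in enumerate(cohort):
        best_g, best_corr, _ = dmf_fit_G(sc, fc, params, settings, grid)
        per_subject[sc.subject_id or f"subject{idx}"] = (best_g, best_corr)
        counts[int(np.argmin(np.abs(grid - best_g)))] += 1
    return float(grid[int(np.argmax(counts))]), per_subject


def dmf_fixed_point(params: DMFParameters, s_bracket=(0.0, 1.0)) -> float:
    """Deterministic uncoupled fixed point of the scalar gating equation.

    Solves S/tau_S = (1 - S) gamma H(w J_N S + I_0) by bisection; used as
    the reference the integrated steady state must reach when G = 0 and
    sigma = 0.
    """
    from scipy.optimize import brentq

    def resid(S):
        x = params.w * params.J_N * S + params.I_0
        return (-S / params.tau_S
                + (1.0 - S) * params.gamma_kinetic * float(firing_rate(x, params)))

    return float(brentq(resid, *s_bracket, xtol=1e-12))
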