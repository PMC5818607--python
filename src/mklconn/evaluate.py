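"""Model evaluation and robustness battery.

Scores are Pearson correlations between predicted and empirical FC over
the off-diagonal upper triangle (the diagonal is 1 by construction and
carries no information).  The battery mirrors the standard checks for a
learned structure-function mapping: cross-validation protocols, SC edge
thresholding, SC perturbation nulls, and two permutation tests on the
learned co-activation stack (scale swaps and row permutations).
"""

from __future__ import annotations

import warnings

import numpy as np

from .mkl import fit_mkl, predict_fc
from .types import (
    CoactivationStack,
    EvaluationReport,
    FunctionalConnectome,
    ModelFactory,
    PredictedFC,
    StructuralConnectome,
    Subject,
    TrainingCohort,
    UndefinedCorrelationError,
    ValidationError,
)

PROTOCOLS = ("holdout_half", "loo", "kfold")

#: Edge-retention levels (percent of strongest edges kept) for the
#: thresholding experiment.
DEFAULT_THRESHOLD_GRID = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0)


def _offdiag(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    return values[iu]


def fc_correlation(predicted: PredictedFC | FunctionalConnectome,
                   empirical: FunctionalConnectome) -> float:
    """Pearson correlation between off-diagonal upper-triangle entries.

    Both matrices are symmetrized first so each region pair contributes one
    value.  Raises :class:`UndefinedCorrelationError` if either off-diagonal
    vector has zero variance.
    """
    P = predicted.values
    P = 0.5 * (P + P.T)
    E = empirical.values
    if P.shape != E.shape:
        raise ValidationError(f"shape mismatch {P.shape} vs {E.shape}")
    x, y = _offdiag(P), _offdiag(E)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance off-diagonal vector")
    return float(np.corrcoef(x, y)[0, 1])


def mkl_model_factory(lam: float | str = "auto", seed: int = 0) -> ModelFactory:
    """Factory adapter fitting the multi-kernel model inside a protocol."""

    def factory(train: list[Subject]):
        cohort = TrainingCohort([(s.bank, s.fc) for s in train])
        stack = fit_mkl(cohort, lam=lam, seed=seed)
        return lambda subject: predict_fc(subject.bank, stack)

    return factory


def sdk_model_factory(scale_grid: np.ndarray) -> ModelFactory:
    """Factory adapter fitting the single-kernel baseline inside a protocol."""
    from .sdk import sdk_fit_cohort, sdk_predict  # local import: no cycle

    def factory(train: list[Subject]):
        model = sdk_fit_cohort([(s.spec, s.fc) for s in train], scale_grid)
        return lambda subject: sdk_predict(subject.spec, model)

    return factory


def cross_validate(
    subjects: list[Subject],
    model_factory: ModelFactory,
    protocol: str = "kfold",
    seed: int = 0,
    k: int = 5,
) -> EvaluationReport:
    """Run one cross-validation protocol and score every test subject.

    Protocols: ``holdout_half`` (random half train / half test),
    ``loo`` (leave-one-out), ``kfold`` (k shuffled folds).  All splits are
    deterministic functions of ``seed``.
    """
    p = len(subjects)
    if protocol not in PROTOCOLS:
        raise ValidationError(f"unknown protocol {protocol!r}")
    if p < 2 or (protocol == "kfold" and p < k):
        raise ValidationError(f"too few subjects ({p}) for protocol {protocol}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(p)
    if protocol == "holdout_half":
        splits = [(order[: p // 2], order[p // 2:])]
    elif protocol == "loo":
        splits = [(np.delete(np.arange(p), i), np.array([i])) for i in range(p)]
    else:
        folds = np.array_split(order, k)
        splits = [
            (np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
            for i in range(k)
        ]
    per_subject: dict[str, float] = {}
    fold_of: dict[str, int] = {}
    for fold_idx, (train_idx, test_idx) in enumerate(splits):
        predictor = model_factory([subjects[int(i)] for i in train_idx])
        for i in test_idx:
            subj = subjects[int(i)]
            per_subject[subj.subject_id] = fc_correlation(predictor(subj), subj.fc)
            fold_of[subj.subject_id] = fold_idx
    return EvaluationReport.from_scores(per_subject, protocol=protocol,
                                        folds=fold_of, seed=seed)


def threshold_sc(sc: StructuralConnectome, top_percent: float) -> StructuralConnectome:
    """Keep only the strongest top_percent % of undirected edges.

    Edges are ranked by weight descending; floor(top_percent/100 * E) of
    the E nonzero undirected edges survive (at least one), with ties at the
    cutoff broken by (i, j) lexicographic order.  If the pruning isolates a node the result
    carries a warning flag (``isolated_nodes``) instead of failing, since
    degraded prediction on over-thresholded graphs is itself a finding.
    """
    if not (0 < top_percent <= 100):
        raise ValidationError("top_percent must be in (0, 100]")
    W = sc.weights
    n = sc.n
    iu = np.triu_indices(n, k=1)
    weights = W[iu]
    nz = np.flatnonzero(weights > 0)
    keep_count = max(1, int(np.floor(top_percent / 100.0 * nz.size + 1e-9)))
    # sort by (-weight, i, j): descending weight, lexicographic ties
    order = sorted(nz, key=lambda e: (-weights[e], iu[0][e], iu[1][e]))
    kept = order[:keep_count]
    W_new = np.zeros_like(W)
    rows = iu[0][kept]
    cols = iu[1][kept]
    W_new[rows, cols] = W[rows, cols]
    W_new = W_new + W_new.T
    out = StructuralConnectome.from_weights(
        W_new, sc.region_labels, subject_id=sc.subject_id, allow_isolated=True)
    if out.isolated_nodes:
        warnings.warn(
            f"thresholding at {top_percent}% isolated node(s) "
            f"{out.isolated_nodes}", RuntimeWarning, stacklevel=2)
    return out


def perturb_sc(sc: StructuralConnectome, seed: int,
               avoid_isolated: bool = False) -> StructuralConnectome:
    """Weight-multiset-preserving random perturbation of an SC.

    The off-diagonal upper-triangle weights (zeros included) are permuted
    uniformly across all upper-triangle positions and mirrored, so the edge
    weight multiset is preserved exactly while all topological structure
    (degree sequence, modules) is destroyed.  With ``avoid_isolated`` the
    null is conditioned on every node keeping positive degree (redrawn up to
    100 times), which keeps the perturbed graph usable by spectral code.
    """
    rng = np.random.default_rng(seed)
    n = sc.n
    iu = np.triu_indices(n, k=1)
    vals = sc.weights[iu]
    attempts = 100 if avoid_isolated else 1
    for _ in range(attempts):
        perm = rng.permutation(vals.size)
        W = np.zeros_like(sc.weights)
        W[iu] = vals[perm]
        W = W + W.T
        if not avoid_isolated or np.all(W.sum(axis=1) > 0):
            return StructuralConnectome.from_weights(
                W, sc.region_labels, subject_id=sc.subject_id,
                allow_isolated=True)
    raise ValidationError(
        "could not draw an isolation-free perturbation in 100 attempts")


def _mean_score(stack: CoactivationStack, cohort: list[Subject]) -> float:
    return float(np.mean([
        fc_correlation(predict_fc(s.bank, stack), s.fc) for s in cohort
    ]))


def swap_pi_test(stack: CoactivationStack, test_cohort: list[Subject]) -> list[float]:
    """Scale-specificity test: swap each pi_i with pi_m, score, repeat.

    Entry i is the test-cohort mean correlation after swapping pi_i with
    the last matrix pi_m; entry m (the self-swap) is exactly the unswapped
    baseline.  A sharp drop for distant scales indicates that the learned
    matrices are genuinely scale-specific.
    """
    m = stack.m
    scores = []
    for i in range(m):
        pis = [p.copy() for p in stack.pis]
        pis[i], pis[m - 1] = pis[m - 1], pis[i]
        swapped = CoactivationStack.from_stacked(
            np.vstack(pis), stack.scale_set, lam=stack.lam)
        scores.append(_mean_score(swapped, test_cohort))
    return scores


def permute_pi_rows_test(
    stack: CoactivationStack,
    test_cohort: list[Subject],
    n_perm: int = 250,
    seed: int = 0,
) -> list[float]:
    """Null distribution from uniformly permuting the mn rows of Pi.

    Each of ``n_perm`` draws permutes rows of the stacked Pi (destroying
    the region/scale correspondence while preserving the entries), scores
    the test cohort, and records the mean correlation.
    """
    rng = np.random.default_rng(seed)
    mn = stack.stacked.shape[0]
    scores = []
    for _ in range(n_perm):
        perm = rng.permutation(mn)
        permuted = CoactivationStack.from_stacked(
            stack.stacked[perm], stack.scale_set, lam=stack.lam)
        scores.append(_mean_score(permuted, test_cohort))
    return scores


def seed_correlation_map(
    fc: FunctionalConnectome | PredictedFC, seed_region: int
) -> np.ndarray:
    """Correlation of one seed region with every region (a matrix row).

    For empirical FC the self-entry is 1 by construction; for predictions
    the symmetrized row is returned as-is.
    """
    V = fc.values
    V = 0.5 * (V + V.T)
    if not (0 <= seed_region < V.shape[0]):
        raise ValidationError(f"seed region {seed_region} out of range")
    return V[seed_region].copy()
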