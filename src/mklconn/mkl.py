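"""Multiple-kernel-learning model of structure-function coupling.

The forward model predicts a subject's functional connectivity as a
combination of that subject's diffusion kernels, each post-multiplied by a
scale-specific co-activation matrix shared across the cohort:

    C_f = sum_{i=1}^{m} H_i pi_i = [H_1 ... H_m] Pi.

Training minimizes, independently for each region column j,

    || X Pi^j - Y_j ||^2 + lambda ||Pi^j||_1,

where X (pn x mn) vertically stacks the p subjects' kernel banks and Y_j
concatenates column j of their empirical FCs.  The L1 penalty keeps the
number of co-activating region pairs small; the n column problems are
solved by coordinate-descent LASSO with no intercept and no column
standardization (the kernels already share a spectral footing).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .types import (
    CoactivationStack,
    DiffusionKernelBank,
    PredictedFC,
    TrainingCohort,
    ValidationError,
)

_LASSO_TOL = 1e-7  # duality-gap tolerance (relative, sklearn convention)
_LASSO_MAX_ITER = 100_000


def assemble_design(cohort: TrainingCohort) -> tuple[np.ndarray, np.ndarray]:
    """Stack the cohort into the regression design (X, Y).

    X is (pn x mn): subject s contributes row block [H_1^s ... H_m^s].
    Y is (pn x n): subject s contributes its empirical FC; column j of Y
    concatenates FC column f_j^s over subjects.
    """
    X = np.vstack([bank.stacked for bank, _ in cohort.subjects])
    Y = np.vstack([fc.values for _, fc in cohort.subjects])
    return X, Y


def fit_column(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve one column problem argmin ||X w - y||^2 + lam ||w||_1.

    lam = 0 falls back to least squares (minimum-norm solution).  The
    penalized problem is handed to coordinate-descent LASSO; note the solver
    objective (1/(2N))||y - Xw||^2 + alpha ||w||_1 maps to ours with
    alpha = lam / (2N).  No intercept, no standardization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if lam < 0:
        raise ValidationError("L1 penalty lambda must be nonnegative")
    if X.shape[0] != y.shape[0]:
        raise ValidationError(f"design rows {X.shape[0]} != target length {y.shape[0]}")
    if lam == 0:
        w, *_ = np.linalg.lstsq(X, y, rcond=None)
        return w
    model = Lasso(alpha=lam / (2.0 * X.shape[0]), fit_intercept=False,
                  tol=_LASSO_TOL, max_iter=_LASSO_MAX_ITER)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    for c in caught:
        if issubclass(c.category, ConvergenceWarning):
            warnings.warn(
                f"LASSO column did not reach tol={_LASSO_TOL} in "
                f"{_LASSO_MAX_ITER} iterations (lam={lam:.3g}); "
                "returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
    return model.coef_.copy()


def lasso_objective(X: np.ndarray, w: np.ndarray, y: np.ndarray, lam: float) -> float:
    """The column objective ||Xw - y||^2 + lam ||w||_1."""
    r = X @ w - y
    return float(r @ r + lam * np.abs(w).sum())


def training_objective(X: np.ndarray, Y: np.ndarray,
                       stack: CoactivationStack, lam: float) -> float:
    """Total objective; equals the sum of the n column objectives."""
    return sum(lasso_objective(X, stack.stacked[:, j], Y[:, j], lam)
               for j in range(Y.shape[1]))


def _lambda_grid(X: np.ndarray, Y: np.ndarray, size: int = 8) -> np.ndarray:
    # Largest useful penalty: above max_j ||2 X^T Y_j||_inf every column is 0.
    lam_max = max(float(np.abs(2.0 * X.T @ Y[:, j]).max())
                  for j in range(Y.shape[1]))
    return np.geomspace(lam_max * 1e-4, lam_max, size)


def select_lambda(cohort: TrainingCohort, seed: int = 0, n_folds: int = 3,
                  grid: np.ndarray | None = None) -> float:
    """Pick lambda by inner k-fold cross-validated prediction MSE.

    Subjects (not rows) are the cross-validation unit; folds are a
    deterministic shuffle of subject indices from ``seed``.  Ties prefer the
    larger (sparser) lambda.
    """
    p = cohort.p
    if p < n_folds:
        n_folds = max(2, p)
    if p < 2:
        raise ValidationError("lambda selection needs at least 2 subjects")
    X_full, Y_full = assemble_design(cohort)
    if grid is None:
        grid = _lambda_grid(X_full, Y_full)
    order = np.random.default_rng(seed).permutation(p)
    folds = np.array_split(order, n_folds)
    n = cohort.n
    errs = np.zeros(len(grid))
    for fold in folds:
        test = set(int(i) for i in fold)
        train_idx = [s for s in range(p) if s not in test]
        rows_tr = np.concatenate([np.arange(s * n, (s + 1) * n) for s in train_idx])
        rows_te = np.concatenate([np.arange(s * n, (s + 1) * n) for s in sorted(test)])
        X_tr, Y_tr = X_full[rows_tr], Y_full[rows_tr]
        X_te, Y_te = X_full[rows_te], Y_full[rows_te]
        for gi, lam in enumerate(grid):
            Pi = np.column_stack([fit_column(X_tr, Y_tr[:, j], lam)
                                  for j in range(n)])
            errs[gi] += float(np.mean((X_te @ Pi - Y_te) ** 2))
    # argmax over reversed grid -> largest lambda among minimizers
    best = len(grid) - 1 - int(np.argmin(errs[::-1]))
    return float(grid[best])


def fit_mkl(cohort: TrainingCohort, lam: float | str = "auto",
            seed: int = 0) -> CoactivationStack:
    """Learn the co-activation stack Pi from a training cohort.

    The n region columns are fitted independently (the Frobenius objective
    separates over columns).  ``lam="auto"`` selects the penalty by inner
    3-fold cross-validation over training subjects with a deterministic
    split from ``seed``; the chosen value is recorded on the returned stack.
    """
    X, Y = assemble_design(cohort)
    if isinstance(lam, str):
        if lam != "auto":
            raise ValidationError(f"unknown lambda mode {lam!r}")
        lam_value = select_lambda(cohort, seed=seed)
    else:
        lam_value = float(lam)
        if lam_value < 0:
            raise ValidationError("L1 penalty lambda must be nonnegative")
    Pi = np.column_stack([fit_column(X, Y[:, j], lam_value)
                          for j in range(cohort.n)])
    return CoactivationStack.from_stacked(Pi, cohort.scale_set, lam=lam_value)


def predict_fc(bank: DiffusionKernelBank, stack: CoactivationStack,
               symmetrize: bool = True) -> PredictedFC:
    """Forward model: C_f = sum_i H_i pi_i = [H_1 ... H_m] Pi.

    The raw sum is not symmetric for general pi_i while empirical FC is, so
    by default the prediction is symmetrized to (C_f + C_f^T)/2, giving one
    value per region pair.
    """
    if not bank.scale_set.allclose(stack.scale_set):
        raise ValidationError("kernel bank and stack use different scale sets")
    C = bank.stacked @ stack.stacked
    if symmetrize:
        C = 0.5 * (C + C.T)
    return PredictedFC(values=C, symmetrized=symmetrize)
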