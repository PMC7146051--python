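"""LASSO solver and the two-stage Random LASSO bootstrap selector.

The solver minimizes the standard scaled objective

    (1/(2n))·||y − Xb||² + λ·Σ_j |b_j|

by cyclic coordinate descent with soft-thresholding.  The un-normalized
penalized residual form ``||g − Gb||² + λ'·|b|`` maps onto this convention
by λ = λ' / (2n); all λ values in this package are on the scaled form.

Random LASSO is a two-step bootstrap procedure for stable sparse selection
in p ≈ n or p > n regimes:

1. *Importance (reputation) generation* — B1 times, draw a bootstrap sample
   of the observations and a uniform random subset of q1 candidate
   predictors, fit a LASSO on that submatrix, and record the coefficients
   (zero for non-candidates).  The importance of predictor j is the
   absolute value of its mean recorded coefficient.
2. *Importance-weighted selection* — B2 times, bootstrap the observations
   and draw q2 candidates with probability proportional to importance, fit
   a LASSO, and average the recorded coefficients; entries below
   ``zero_threshold`` (default 1/n) are set exactly to zero.

All randomness flows from a single seed through a fixed generator-split
scheme — stream (seed, stage, b) for bootstrap b of each stage — so
changing B1 does not perturb the selection-stage draws and vice versa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._cd import cd_gaussian

logger = logging.getLogger(__name__)

_STAGE_CV, _STAGE_IMPORTANCE, _STAGE_SELECT = 0, 1, 2


@dataclass
class LassoFit:
    """Solution of one penalized least-squares problem.

    ``objective`` is the value of (1/(2n))||y − Xb||² + λ||b||₁ at the
    returned coefficients (never above its value at b = 0); ``residuals``
    is y − intercept − Xb on the training data.
    """

    coefficients: np.ndarray
    intercept: float
    lam: float
    objective: float
    n_iter: int
    converged: bool
    residuals: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.coefficients)[0]


@dataclass
class RandomLassoConfig:
    """Knobs of the two-step procedure.

    ``q1``/``q2`` default to ⌈p/3⌉ when None; ``zero_threshold`` defaults
    to 1/n; ``lambda_rule`` is "cv" (5-fold CV over a 50-point log grid,
    run once per call and reused across bootstrap fits) or "fixed"
    (use ``lambda_fixed``).
    """

    b1: int = 200
    b2: int = 200
    q1: int | None = None
    q2: int | None = None
    zero_threshold: float | None = None
    lambda_rule: str = "cv"
    lambda_fixed: float | None = None
    seed: int = 0
    identity_bootstrap: bool = False  # test mode: no observation resampling

    def __post_init__(self) -> None:
        if self.b1 < 1 or self.b2 < 1:
            raise ValueError("b1 and b2 must be >= 1")
        if self.lambda_rule not in ("cv", "fixed"):
            raise ValueError("lambda_rule must be 'cv' or 'fixed'")
        if self.lambda_rule == "fixed" and self.lambda_fixed is None:
            raise ValueError("lambda_fixed required when lambda_rule='fixed'")

    def resolve_q(self, p: int) -> tuple[int, int]:
        q1 = self.q1 if self.q1 is not None else int(np.ceil(p / 3))
        q2 = self.q2 if self.q2 is not None else int(np.ceil(p / 3))
        if q1 > p or q2 > p:
            raise ValueError(f"q1/q2 ({q1}/{q2}) exceed p={p}")
        return q1, q2


def _check_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError(f"incompatible shapes X{X.shape}, y{y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    return X, y


def lasso_solve(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    fit_intercept: bool = True,
    standardize: bool = False,
    warm_start: np.ndarray | None = None,
) -> LassoFit:
    """Solve the LASSO by cyclic coordinate descent.

    With ``standardize=True`` the columns are scaled to unit population SD
    internally and the coefficients back-transformed to the original scale
    (λ then applies on the standardized scale, keeping the penalty
    comparable across predictors).  Non-convergence within ``max_iter``
    sweeps is flagged on the returned fit, not raised.
    """
    X, y = _check_design(X, y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape

    if fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xw = X - x_mean
        yw = y - y_mean
    else:
        x_mean = np.zeros(p)
        y_mean = 0.0
        Xw, yw = X.copy(), y.copy()

    if standardize:
        scale = Xw.std(axis=0)
        scale[scale == 0] = 1.0
        Xw = Xw / scale
    else:
        scale = np.ones(p)

    b = np.zeros(p) if warm_start is None else (warm_start * scale).astype(float)
    n_iter, converged, obj_path = cd_gaussian(
        np.asfortranarray(Xw), yw, float(lam), b, int(max_iter), float(tol)
    )
    if not converged:
        logger.warning("lasso_solve: max_iter=%d reached without convergence", max_iter)
    # exact coordinate minimization makes the objective monotone; guard anyway
    if len(obj_path) > 1 and np.any(np.diff(obj_path) > 1e-10):
        raise AssertionError("coordinate-descent objective increased across sweeps")

    coef = b / scale
    intercept = y_mean - float(x_mean @ coef)
    resid = y - intercept - X @ coef
    objective = 0.5 * float(resid @ resid) / n + lam * float(np.abs(b).sum())
    return LassoFit(coef, intercept, float(lam), objective, int(n_iter),
                    bool(converged), resid)


def kkt_check(X: np.ndarray, y: np.ndarray, fit: LassoFit, tol: float = 1e-6) -> float:
    """Worst stationarity violation of a fit: |x_jᵀr/n − λ·sign(b_j)| on the
    active set, max(|x_jᵀr/n| − λ, 0) elsewhere.  Zero (≤ tol) at an optimum.

    Only valid for fits on pre-standardized designs (where no internal
    rescaling occurred); ``tol`` is the caller's pass threshold, returned
    violations can be compared against it directly.
    """
    X, y = _check_design(X, y)
    r = y - fit.intercept - X @ fit.coefficients
    n = X.shape[0]
    g = X.T @ r / n
    b = fit.coefficients
    active = b != 0
    v_active = np.abs(g[active] - fit.lam * np.sign(b[active]))
    v_inactive = np.maximum(np.abs(g[~active]) - fit.lam, 0.0)
    worst = 0.0
    if v_active.size:
        worst = max(worst, float(v_active.max()))
    if v_inactive.size:
        worst = max(worst, float(v_inactive.max()))
    return worst


def lambda_max(X: np.ndarray, y: np.ndarray, fit_intercept: bool = True) -> float:
    """Smallest λ at which the LASSO solution is exactly zero.

    Equals max_j |x_jᵀ y| / n on centered data: above it, the zero vector
    satisfies the stationarity conditions.
    """
    X, y = _check_design(X, y)
    n = X.shape[0]
    if fit_intercept:
        X = X - X.mean(axis=0)
        y = y - y.mean()
    return float(np.max(np.abs(X.T @ y)) / n) if X.shape[1] else 0.0


def lasso_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, **kwargs
) -> np.ndarray:
    """Fit a decreasing λ sequence with warm starts; rows are coefficients."""
    lambdas = np.asarray(lambdas, dtype=float)
    out = np.zeros((len(lambdas), X.shape[1]))
    warm = None
    for k, lam in enumerate(lambdas):
        fit = lasso_solve(X, y, lam, warm_start=warm, **kwargs)
        out[k] = fit.coefficients
        warm = fit.coefficients
    return out


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 50,
                        min_ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        return np.zeros(1)
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def select_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    n_lambdas: int = 50,
    min_ratio: float = 1e-3,
    seed: int = 0,
    rule: str = "min",
) -> float:
    """Pick λ by 5-fold cross-validated mean squared error.

    The grid is 50 log-spaced points from λ_max down to 1e−3·λ_max; folds
    are a seeded random partition of the observations.  ``rule="min"``
    returns the MSE-minimizing λ (best for prediction); ``rule="1se"``
    returns the largest λ whose CV error is within one standard error of
    the minimum — the sparser choice used for support selection.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    X, y = _check_design(X, y)
    n = X.shape[0]
    n_folds = min(n_folds, n)
    grid = default_lambda_grid(X, y, n_lambdas, min_ratio)
    if grid[0] <= 0:
        return 0.0
    rng = np.random.default_rng([seed, _STAGE_CV])
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    fold_err = np.zeros((len(folds), len(grid)))
    for fi, val_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Xva, yva = X[val_idx], y[val_idx]
        warm = None
        for k, lam in enumerate(grid):
            fit = lasso_solve(Xtr, ytr, lam, warm_start=warm)
            warm = fit.coefficients
            pred = fit.intercept + Xva @ fit.coefficients
            fold_err[fi, k] = float(((yva - pred) ** 2).mean())
    cv_err = fold_err.mean(axis=0)
    k_min = int(np.argmin(cv_err))
    if rule == "min":
        return float(grid[k_min])
    se = float(fold_err[:, k_min].std(ddof=1) / np.sqrt(len(folds)))
    within = np.nonzero(cv_err <= cv_err[k_min] + se)[0]
    return float(grid[int(within.min())])  # grid is decreasing: min index = largest λ


# A bootstrap sample of size n holds ≈ (1 − e⁻¹)·n distinct observations;
# the penalty level appropriate for a subfit therefore scales up by
# √(1/0.632) relative to a λ cross-validated on the full data.
_BOOTSTRAP_LAMBDA_SCALE = 1.0 / np.sqrt(1.0 - np.exp(-1.0))


def _resolve_lambda(X, y, config: RandomLassoConfig) -> float:
    if config.lambda_rule == "fixed":
        return float(config.lambda_fixed)
    # 1-SE rule: sparse-support CV choice, shared by all bootstrap subfits
    lam = select_lambda_cv(X, y, seed=config.seed, rule="1se")
    return lam * _BOOTSTRAP_LAMBDA_SCALE


def _bootstrap_indices(rng: np.random.Generator, y: np.ndarray,
                       max_retries: int = 10) -> np.ndarray:
    n = len(y)
    for _ in range(max_retries):
        idx = rng.integers(0, n, size=n)
        if np.ptp(y[idx]) > 0:
            return idx
    raise RuntimeError("bootstrap response variance zero after 10 retries")


def random_lasso_importance(
    X: np.ndarray, y: np.ndarray, config: RandomLassoConfig
) -> np.ndarray:
    """Stage 1: per-predictor importance I_j = |mean bootstrap coefficient|."""
    X, y = _check_design(X, y)
    n, p = X.shape
    q1, _ = config.resolve_q(p)
    lam = _resolve_lambda(X, y, config)
    coef_sum = np.zeros(p)
    for b in range(config.b1):
        rng = np.random.default_rng([config.seed, _STAGE_IMPORTANCE, b])
        idx = (np.arange(n) if config.identity_bootstrap
               else _bootstrap_indices(rng, y))
        cand = rng.choice(p, size=q1, replace=False)
        fit = lasso_solve(X[np.ix_(idx, cand)], y[idx], lam, standardize=True)
        coef_sum[cand] += fit.coefficients
    return np.abs(coef_sum / config.b1)


def _weighted_candidates(rng: np.random.Generator, importances: np.ndarray,
                         q2: int) -> np.ndarray:
    p = len(importances)
    pos = np.nonzero(importances > 0)[0]
    if len(pos) == 0:
        return rng.choice(p, size=q2, replace=False)
    if len(pos) >= q2:
        probs = importances[pos] / importances[pos].sum()
        return pos[rng.choice(len(pos), size=q2, replace=False, p=probs)]
    # fewer positive-importance predictors than q2: take them all and pad
    rest = np.setdiff1d(np.arange(p), pos)
    pad = rng.choice(rest, size=q2 - len(pos), replace=False)
    return np.concatenate([pos, pad])


def random_lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    importances: np.ndarray,
    config: RandomLassoConfig,
) -> np.ndarray:
    """Stage 2: importance-weighted bootstrap refitting and averaging."""
    X, y = _check_design(X, y)
    n, p = X.shape
    importances = np.asarray(importances, dtype=float)
    if importances.shape != (p,) or np.any(importances < 0):
        raise ValueError("importances must be a nonnegative length-p vector")
    if not np.any(importances > 0):
        warnings.warn("all-zero importances: falling back to uniform sampling")
    _, q2 = config.resolve_q(p)
    zero_threshold = (config.zero_threshold if config.zero_threshold is not None
                      else 1.0 / n)
    lam = _resolve_lambda(X, y, config)
    coef_sum = np.zeros(p)
    for b in range(config.b2):
        rng = np.random.default_rng([config.seed, _STAGE_SELECT, b])
        idx = (np.arange(n) if config.identity_bootstrap
               else _bootstrap_indices(rng, y))
        cand = _weighted_candidates(rng, importances, q2)
        fit = lasso_solve(X[np.ix_(idx, cand)], y[idx], lam, standardize=True)
        coef_sum[cand] += fit.coefficients
    coef = coef_sum / config.b2
    coef[np.abs(coef) < zero_threshold] = 0.0
    return coef


def random_lasso(X: np.ndarray, y: np.ndarray,
                 config: RandomLassoConfig) -> np.ndarray:
    """Full two-step Random LASSO: importance generation then selection."""
    imp = random_lasso_importance(X, y, config)
    return random_lasso_select(X, y, imp, config)
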