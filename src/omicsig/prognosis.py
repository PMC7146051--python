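"""Prognostic-signature construction and cross-validated evaluation.

The signature is the multi-omics analogue of a coefficient table: per
omics layer, differentially expressed features are ranked by a bootstrap
(Random-LASSO-style) importance computed under the logistic loss against
the survival-group label, truncated to a fixed per-layer size — the
feature-elimination step, defaulting to 5 lncRNAs, 11 miRNAs, 30 mRNAs,
4 methylations and 3 proteins — and a single L1-penalized logistic model
is then refit on the concatenated kept features.

Evaluation is fivefold leave-group (stratified) cross-validation: folds
are stratified on the survival-group label; inside each training fold the
classes are balanced by bootstrap resampling to the larger class size, the
whole screen → rank → refit chain is rebuilt from scratch, and the held-out
fold is scored.  Accuracy, error rate and the Matthews correlation
coefficient are computed from the aggregated confusion counts (the report
also carries per-fold values).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ExpressionMatrix
from .diffexpr import moderated_t, select_de_features
from .sparse import _check_design

logger = logging.getLogger(__name__)

DEFAULT_LAYER_SIZES = {"lncRNA": 5, "miRNA": 11, "mRNA": 30,
                       "methylation": 4, "protein": 3}


# ---------------------------------------------------------------------------
# L1-penalized logistic regression (FISTA proximal gradient)
# ---------------------------------------------------------------------------

@dataclass
class LogisticLassoFit:
    coefficients: np.ndarray
    intercept: float
    lam: float
    objective: float
    n_iter: int
    converged: bool


def _nll(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable mean of log(1 + e^eta) - y*eta
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def logistic_lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> LogisticLassoFit:
    """Minimize mean logistic NLL + λ·Σ|b_j| (intercept unpenalized).

    FISTA with soft-threshold proximal steps on the slopes and plain
    gradient steps on the intercept; the step size is the inverse of the
    Lipschitz bound ||[1, X]||₂²/(4n).  At λ large enough all slopes are
    zero and the intercept is the empirical log-odds.  Complete separation
    at λ = 0 yields diverging coefficients; a warning is emitted when the
    iterate norm grows very large and the penalty is relied upon otherwise.
    """
    X, y = _check_design(X, y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all() or len(classes) < 2:
        raise ValueError("y must contain both classes, coded 0/1")
    n, p = X.shape
    aug = np.hstack([np.ones((n, 1)), X])
    L = np.linalg.norm(aug, 2) ** 2 / (4.0 * n)
    step = 1.0 / L

    b = np.zeros(p)
    b0 = float(np.log(y.mean() / (1 - y.mean())))
    zb, zb0 = b.copy(), b0
    t_acc = 1.0
    prev_obj = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = zb0 + X @ zb
        prob = 1.0 / (1.0 + np.exp(-eta))
        g = (prob - y) / n
        grad_b = X.T @ g
        grad_b0 = float(g.sum())
        b_new = np.sign(zb - step * grad_b) * np.maximum(
            np.abs(zb - step * grad_b) - step * lam, 0.0)
        b0_new = zb0 - step * grad_b0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2))
        zb = b_new + (t_acc - 1.0) / t_new * (b_new - b)
        zb0 = b0_new + (t_acc - 1.0) / t_new * (b0_new - b0)
        b, b0, t_acc = b_new, b0_new, t_new
        obj = _nll(b0 + X @ b, y) + lam * float(np.abs(b).sum())
        if abs(prev_obj - obj) < tol * max(1.0, abs(obj)):
            converged = True
            break
        prev_obj = obj
    if lam == 0 and float(np.abs(b).sum()) > 1e3:
        warnings.warn("possible complete separation at lambda=0; "
                      "coefficients may diverge")
    objective = _nll(b0 + X @ b, y) + lam * float(np.abs(b).sum())
    return LogisticLassoFit(b, b0, float(lam), objective, it, converged)


def logistic_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """λ above which the penalized logistic slopes are all zero."""
    X, y = _check_design(X, y)
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n) if X.shape[1] else 0.0


def select_logistic_lambda_cv(
    X: np.ndarray, y: np.ndarray,
    n_folds: int = 5, n_lambdas: int = 30, min_ratio: float = 1e-2,
    seed: int = 0,
) -> float:
    """λ minimizing cross-validated mean deviance on a log grid."""
    X, y = _check_design(X, y)
    n = X.shape[0]
    lmax = logistic_lambda_max(X, y)
    if lmax <= 0:
        return 0.0
    grid = np.geomspace(lmax, lmax * min_ratio, n_lambdas)
    rng = np.random.default_rng([seed, 41])
    # stratified folds so both classes appear in every training split
    folds = _stratified_folds(y, min(n_folds, int(min(y.sum(), n - y.sum()))), rng)
    cv = np.zeros(len(grid))
    for val_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        for k, lam in enumerate(grid):
            fit = logistic_lasso_fit(X[mask], y[mask], lam,
                                     tol=1e-7, max_iter=2000)
            eta = fit.intercept + X[val_idx] @ fit.coefficients
            cv[k] += _nll(eta, y[val_idx]) * len(val_idx)
    cv /= n
    return float(grid[int(np.argmin(cv))])


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    k = max(2, k)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.asarray(sorted(f), dtype=int) for f in folds]


# ---------------------------------------------------------------------------
# Signature construction
# ---------------------------------------------------------------------------

@dataclass
class SignatureConfig:
    """Settings of the screen → rank → refit chain."""

    layer_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_SIZES))
    de_alpha: float = 0.05
    de_top_k: int | None = None
    n_bootstrap: int = 100        # importance-stage bootstrap count
    subset_fraction: float = 1 / 3  # candidate-subset size as fraction of p
    seed: int = 0


@dataclass
class SignatureModel:
    """Fitted multi-omics signature: per-layer features with coefficients."""

    layer_features: dict[str, list[str]]
    coefficients: pd.DataFrame     # layer, feature_id, coefficient
    intercept: float
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    positive_label: str = "poor"

    def decision_scores(self, cohort: Cohort) -> np.ndarray:
        """Linear predictor (log-odds of the poor group) per sample."""
        X = _stack_features(cohort, self.layer_features)
        Xs = (X - self.feature_means) / self.feature_sds
        beta = self.coefficients["coefficient"].to_numpy()
        return self.intercept + Xs @ beta

    def predict_labels(self, cohort: Cohort) -> np.ndarray:
        scores = self.decision_scores(cohort)
        return np.where(scores > 0, self.positive_label, "good")


def _stack_features(cohort: Cohort, layer_features: dict[str, list[str]]) -> np.ndarray:
    """Samples × features block matrix over the selected features."""
    blocks = []
    for layer, feats in layer_features.items():
        if not feats:
            continue
        mat = cohort.layers[layer]
        idx = [mat.feature_ids.index(f) for f in feats]
        blocks.append(mat.values[idx, :].T)
    if not blocks:
        return np.zeros((len(cohort.sample_ids), 0))
    return np.hstack(blocks)


def rank_layer_features(
    matrix: ExpressionMatrix,
    feature_ids: list[str],
    y: np.ndarray,
    config: SignatureConfig,
    layer_seed: int,
) -> list[str]:
    """Bootstrap logistic-LASSO importance ranking of one layer's features.

    Ties in importance are broken by |moderated t| (recomputed on the same
    samples) and then lexicographically by feature ID.
    """
    sub = matrix.subset_features(feature_ids)
    vals = sub.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = ((vals - mean) / sd).T
    n, p = X.shape
    q = max(1, int(np.ceil(p * config.subset_fraction)))
    lam = select_logistic_lambda_cv(X, y, seed=layer_seed)
    coef_sum = np.zeros(p)
    for b in range(config.n_bootstrap):
        rng = np.random.default_rng([layer_seed, 7, b])
        idx = _balanced_class_bootstrap(y, rng)
        cand = rng.choice(p, size=q, replace=False)
        fit = logistic_lasso_fit(X[np.ix_(idx, cand)], y[idx], lam,
                                 tol=1e-7, max_iter=2000)
        coef_sum[cand] += fit.coefficients
    importance = np.abs(coef_sum / config.n_bootstrap)

    groups = np.where(y > 0, "poor", "good")
    abs_t = np.abs(moderated_t(sub, groups).table["t_mod"].to_numpy())
    order = sorted(range(p),
                   key=lambda j: (-importance[j], -abs_t[j], feature_ids[j]))
    return [feature_ids[j] for j in order]


def _balanced_class_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample each class with replacement to the larger class size."""
    idx0 = np.nonzero(y == 0)[0]
    idx1 = np.nonzero(y == 1)[0]
    m = max(len(idx0), len(idx1))
    return np.concatenate([rng.choice(idx0, size=m, replace=True),
                           rng.choice(idx1, size=m, replace=True)])


def build_signature(
    cohort: Cohort,
    de_features: dict[str, list[str]],
    config: SignatureConfig | None = None,
) -> SignatureModel:
    """Rank each layer's DE features, truncate to the layer size, refit.

    Layers with fewer DE features than requested keep them all (with a
    warning).  The final model is a single L1-penalized logistic regression
    of the survival-group label on the concatenated kept features, with λ
    chosen by cross-validated deviance.
    """
    config = config or SignatureConfig()
    y = (cohort.group_labels() == "poor").astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both survival groups must be present")

    kept: dict[str, list[str]] = {}
    for layer, feats in de_features.items():
        size = config.layer_sizes.get(layer, len(feats))
        if size == 0 or not feats:
            kept[layer] = []
            continue
        if len(feats) < size:
            warnings.warn(f"layer {layer!r}: only {len(feats)} DE features "
                          f"for requested size {size}; keeping all")
            size = len(feats)
        layer_seed = int(np.random.SeedSequence(
            [config.seed, zlib.crc32(layer.encode())]).generate_state(1)[0]
            % (2**31))
        ranked = rank_layer_features(cohort.layers[layer], feats, y,
                                     config, layer_seed)
        kept[layer] = ranked[:size]

    X = _stack_features(cohort, kept)
    if X.shape[1] == 0:
        b0 = float(np.log(y.mean() / (1 - y.mean())))
        return SignatureModel(kept, pd.DataFrame(
            columns=["layer", "feature_id", "coefficient"]), b0, 0.0,
            np.zeros(0), np.ones(0))
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    lam = select_logistic_lambda_cv(Xs, y, seed=config.seed)
    fit = logistic_lasso_fit(Xs, y, lam)
    rows = [(layer, f) for layer, feats in kept.items() for f in feats]
    coef_df = pd.DataFrame(rows, columns=["layer", "feature_id"])
    coef_df["coefficient"] = fit.coefficients
    return SignatureModel(kept, coef_df, fit.intercept, lam, mean, sd)


# ---------------------------------------------------------------------------
# Cross-validation and metrics
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    fold_assignments: np.ndarray     # fold index per sample
    fold_confusions: list[dict]      # per-fold TP/FP/TN/FN
    accuracy: float
    error_rate: float
    mcc: float
    per_fold_accuracy: list[float]

    @property
    def best_fold_accuracy(self) -> float:
        return max(self.per_fold_accuracy)

    def to_text(self) -> str:
        lines = ["fold\tTP\tFP\tTN\tFN\taccuracy"]
        for f, c in enumerate(self.fold_confusions):
            lines.append(f"{f}\t{c['tp']}\t{c['fp']}\t{c['tn']}\t{c['fn']}"
                         f"\t{self.per_fold_accuracy[f]:.4f}")
        lines.append(f"aggregate accuracy\t{self.accuracy:.4f}")
        lines.append(f"aggregate error rate\t{self.error_rate:.4f}")
        lines.append(f"aggregate MCC\t{self.mcc:.4f}")
        lines.append(f"best fold accuracy\t{self.best_fold_accuracy:.4f}")
        return "\n".join(lines)


def classification_metrics(tp: int, fp: int, tn: int, fn: int
                           ) -> tuple[float, float, float]:
    """(accuracy, error rate, MCC) from confusion counts.

    MCC is defined as 0 when any marginal factor of its denominator
    vanishes (the degenerate all-one-class cases).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("at least one count must be positive")
    accuracy = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return accuracy, 1.0 - accuracy, float(mcc)


def cross_validate(
    cohort: Cohort,
    signature_config: SignatureConfig | None = None,
    k: int = 5,
    balance: bool = True,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV of the full screen → rank → refit chain.

    Folds are stratified on the survival-group label.  Within each training
    fold the classes are (optionally) balanced by bootstrap resampling to
    the larger class size; DE screening and signature construction are
    redone on the (resampled) training data only, and the held-out fold is
    scored with the fold's model.  Deterministic given the seed.
    """
    signature_config = signature_config or SignatureConfig()
    labels = cohort.group_labels()
    y = (labels == "poor").astype(int)
    n = len(y)
    n_min = int(min(y.sum(), n - y.sum()))
    if k > n_min:
        raise ValueError(f"k={k} exceeds the smaller class size {n_min}")
    rng = np.random.default_rng([seed, 11])
    folds = _stratified_folds(y, k, rng)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(folds):
        assignment[idx] = f

    sample_ids = np.asarray(cohort.sample_ids)
    confusions: list[dict] = []
    per_fold_acc: list[float] = []
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        if balance:
            boot_rng = np.random.default_rng([seed, 13, f])
            train_idx = train_idx[
                _balanced_class_bootstrap(y[train_idx], boot_rng)]
        train_cohort = _resampled_cohort(cohort, sample_ids[train_idx])
        fold_cfg = SignatureConfig(
            layer_sizes=dict(signature_config.layer_sizes),
            de_alpha=signature_config.de_alpha,
            de_top_k=signature_config.de_top_k,
            n_bootstrap=signature_config.n_bootstrap,
            subset_fraction=signature_config.subset_fraction,
            seed=int(np.random.SeedSequence([seed, 17, f]).generate_state(1)[0]
                     % (2**31)),
        )
        de = screen_de_features(train_cohort, alpha=fold_cfg.de_alpha,
                                top_k=fold_cfg.de_top_k)
        model = build_signature(train_cohort, de, fold_cfg)
        val_cohort = cohort.subset_samples(list(sample_ids[val_idx]))
        pred = model.predict_labels(val_cohort)
        truth = val_cohort.group_labels()
        tp = int(((pred == "poor") & (truth == "poor")).sum())
        fp = int(((pred == "poor") & (truth == "good")).sum())
        tn = int(((pred == "good") & (truth == "good")).sum())
        fn = int(((pred == "good") & (truth == "poor")).sum())
        confusions.append({"tp": tp, "fp": fp, "tn": tn, "fn": fn})
        per_fold_acc.append((tp + tn) / len(val_idx))

    agg = {key: sum(c[key] for c in confusions) for key in ("tp", "fp", "tn", "fn")}
    accuracy, error, mcc = classification_metrics(**agg)
    return CVReport(assignment, confusions, accuracy, error, mcc, per_fold_acc)


def screen_de_features(
    cohort: Cohort, alpha: float = 0.05, top_k: int | None = None,
) -> dict[str, list[str]]:
    """Moderated-t DE screen of every layer against the survival groups."""
    groups = cohort.group_labels()
    out = {}
    for layer, mat in cohort.layers.items():
        res = moderated_t(mat, groups)
        out[layer] = select_de_features(res, alpha=alpha, top_k=top_k)
    return out


def _resampled_cohort(cohort: Cohort, sample_ids: np.ndarray) -> Cohort:
    """Cohort restricted to ``sample_ids`` allowing repeats (bootstrap)."""
    unique_needed = pd.Index(sample_ids)
    clin = cohort.clinical.set_index("sample_id").loc[unique_needed].reset_index()
    # bootstrap repeats need fresh unique IDs for the data model
    new_ids = [f"{s}_r{i}" for i, s in enumerate(sample_ids)]
    clin["sample_id"] = new_ids
    layers = {}
    for name, mat in cohort.layers.items():
        col = [mat.sample_ids.index(s) for s in sample_ids]
        layers[name] = ExpressionMatrix(name, list(mat.feature_ids), new_ids,
                                        mat.values[:, col].copy())
    return Cohort(layers, clin)


def write_signature(model: SignatureModel, path) -> None:
    model.coefficients.to_csv(path, sep="\t", index=False, float_format="%.10g")
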