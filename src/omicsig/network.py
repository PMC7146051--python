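"""Group-specific regulatory-network inference by per-feature Random LASSO.

For each survival group separately, every feature g_i is regressed on all
other features of the same layer (samples of that group only) with the
two-step Random LASSO; the coefficient vector b_i becomes row i of the
group's adjacency matrix B = {b_1, …, b_p}ᵀ.  Entry B[i, j] is the effect
of regulator j on target i (a directed edge j → i in the linear model);
the diagonal is structurally zero.  The poor-survival group yields the
"tumor-like" network B^T and the good-survival group B^C, and their
entrywise contrast Δ = B^T − B^C ranks candidate rewired edges.

Per-feature regression recovers (at best) each feature's Markov blanket
and carries no orientation guarantee, so recovery against a known acyclic
truth is scored on the undirected edge skeleton (see :func:`edge_recovery`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, standardize_features
from .sparse import RandomLassoConfig, random_lasso


@dataclass
class AdjacencyMatrix:
    """One group's inferred network: row i = regression of feature i."""

    group_label: str
    feature_ids: list[str]
    B: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.feature_ids)
        if self.B.shape != (p, p):
            raise ValueError(f"B must be {p}×{p}")
        if np.any(np.diag(self.B) != 0):
            raise ValueError("diagonal of B must be exactly zero")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("non-finite entries in B")

    def edges(self) -> pd.DataFrame:
        reg, tgt = np.nonzero(self.B.T)  # (regulator j, target i)
        return pd.DataFrame({
            "regulator_id": [self.feature_ids[j] for j in reg],
            "target_id": [self.feature_ids[i] for i in tgt],
            "weight": self.B[tgt, reg],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=self.feature_ids, columns=self.feature_ids)


def infer_network(
    matrix: ExpressionMatrix,
    config: RandomLassoConfig,
    group_label: str = "",
) -> AdjacencyMatrix:
    """Infer one group's network from that group's (standardized) samples."""
    std = standardize_features(matrix)
    if std.n_features < matrix.n_features:
        raise ValueError("constant features present; filter before inference")
    p = std.n_features
    G = std.values  # features × samples
    B = np.zeros((p, p))
    for i in range(p):
        mask = np.arange(p) != i
        X = G[mask].T  # samples × (p − 1), row i excluded by construction
        y = G[i]
        cfg = replace(
            config,
            seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                     % (2**31)),
        )
        b = random_lasso(X, y, cfg)
        B[i, mask] = b
    return AdjacencyMatrix(group_label, list(std.feature_ids), B)


def infer_group_networks(
    matrix: ExpressionMatrix,
    group_labels: np.ndarray,
    config: RandomLassoConfig,
    poor_label: str = "poor",
    good_label: str = "good",
) -> tuple[AdjacencyMatrix, AdjacencyMatrix]:
    """Infer (B^T, B^C) from the poor- and good-survival samples.

    Each group is re-standardized internally, so between-group mean shifts
    cannot masquerade as edges.  Requires at least q2 + 2 samples per group.
    """
    group_labels = np.asarray(group_labels)
    if group_labels.shape[0] != matrix.n_samples:
        raise ValueError("group_labels length must match samples")
    _, q2 = config.resolve_q(matrix.n_features - 1)
    nets = []
    for label in (poor_label, good_label):
        ids = [s for s, g in zip(matrix.sample_ids, group_labels) if g == label]
        if len(ids) < q2 + 2:
            raise ValueError(
                f"group {label!r} has {len(ids)} samples; needs >= {q2 + 2}"
            )
        nets.append(infer_network(matrix.subset_samples(ids), config, label))
    return nets[0], nets[1]


def differential_edges(
    B_T: AdjacencyMatrix,
    B_C: AdjacencyMatrix,
    delta_threshold: float = 0.0,
) -> pd.DataFrame:
    """Edges whose weight changes between groups: Δ = B^T − B^C.

    Returns rows (regulator_id, target_id, weight_T, weight_C, delta) with
    |Δ| ≥ threshold, sorted by |Δ| descending, ties by (regulator, target).
    """
    if B_T.feature_ids != B_C.feature_ids:
        raise ValueError("feature sets of the two networks differ")
    ids = B_T.feature_ids
    delta = B_T.B - B_C.B
    tgt, reg = np.nonzero(np.abs(delta) >= delta_threshold
                          if delta_threshold > 0
                          else ~np.eye(len(ids), dtype=bool))
    df = pd.DataFrame({
        "regulator_id": [ids[j] for j in reg],
        "target_id": [ids[i] for i in tgt],
        "weight_T": B_T.B[tgt, reg],
        "weight_C": B_C.B[tgt, reg],
        "delta": delta[tgt, reg],
    })
    df["abs_delta"] = df["delta"].abs()
    df = df.sort_values(["abs_delta", "regulator_id", "target_id"],
                        ascending=[False, True, True], kind="stable")
    return df.drop(columns="abs_delta").reset_index(drop=True)


def edge_recovery(
    B_hat: np.ndarray,
    B_true: np.ndarray,
    weight_threshold: float = 0.05,
    rule: str = "and",
) -> dict[str, float]:
    """Precision / sensitivity of inferred vs true edges, on the skeleton.

    Per-feature regressions recover neighborhoods without orientation, so
    the comparison is between undirected pairs {i, j}.  Under the default
    "and" rule a pair is called an edge when |B̂[i, j]| and |B̂[j, i]| both
    exceed ``weight_threshold`` (the symmetrized neighborhood-selection
    convention, which suppresses one-sided noise hits); "or" requires
    either direction.  On standardized expression a coefficient below the
    default 0.05 explains under 0.25% of the target's variance and is
    treated as no edge.  The truth counts a pair as an edge when the
    (acyclic) ground-truth matrix has it in either direction.
    """
    if B_hat.shape != B_true.shape:
        raise ValueError("shape mismatch")
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    A = np.abs(B_hat) > weight_threshold
    est = (A & A.T) if rule == "and" else (A | A.T)
    tru = (B_true != 0) | (B_true.T != 0)
    iu = np.triu_indices(B_hat.shape[0], k=1)
    est, tru = est[iu], tru[iu]
    tp = int((est & tru).sum())
    fp = int((est & ~tru).sum())
    fn = int((~est & tru).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "sensitivity": sensitivity}


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_adjacency(adj: AdjacencyMatrix, path) -> None:
    frame = adj.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")
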