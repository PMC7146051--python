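"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the kind of cohort the pipeline targets — several omics layers
(lncRNA, miRNA, mRNA, methylation, protein) measured on tumor samples with
two survival groups — but with every latent quantity recorded, so that
downstream stages (differential expression, network inference, signature
construction, survival analysis) can be scored against the truth.

Generative model, per layer with p features and n samples:

1. A sparse acyclic regulatory network ``B_true`` is drawn: under a fixed
   feature ordering, each of the p(p−1)/2 ordered pairs (j → i, j < i) is an
   edge independently with probability ``network_density``; nonzero effects
   are uniform on ±[low, high].
2. Survival-group labels (good/poor) are assigned first and drive
   everything downstream.  A ``de_fraction`` subset of features receives a
   mean shift of ``de_effect × noise_sd`` in the poor group.
3. Expression follows the structural recursion
   ``g_i = Σ_{j<i} B[i,j]·g_j + shift_i·1{poor} + ε_i``, ε_i ~ N(0, noise_sd²),
   evaluated in the acyclic ordering, i.e. g = (I − B)⁻¹(shift + ε).
4. Survival times are exponential with log-hazard linear in a set of risk
   features (a subset of the directly shifted features); censoring is
   uniform administrative censoring calibrated to ``censor_rate``.
5. Tumor purity is Beta(a, b) per sample.

Because shifts enter the recursion, descendants of shifted features inherit
attenuated group differences; :meth:`GroundTruth.total_shifts` exposes the
propagated distribution-level shift of every feature.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ExpressionMatrix, write_clinical, write_expression

DEFAULT_LAYERS = {
    "lncRNA": 200, "miRNA": 200, "mRNA": 200, "methylation": 200, "protein": 200,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Simulation parameters; defaults give the strong-signal cohort.

    ``de_effect`` is the group mean shift in units of ``noise_sd``;
    ``purity_beta_params`` (8, 3) put roughly a fifth of samples below the
    0.60 purity cut; ``baseline_hazard`` is per day.
    """

    n_samples: int = 300
    features_per_layer: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LAYERS))
    network_density: float = 0.05
    edge_effect_range: tuple[float, float] = (0.3, 0.8)
    de_fraction: float = 0.2
    de_effect: float = 2.0
    noise_sd: float = 1.0
    purity_beta_params: tuple[float, float] = (8.0, 3.0)
    censor_rate: float = 0.3
    baseline_hazard: float = 1e-3
    risk_weight: float = 0.5
    risk_features_per_layer: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        for name, p in self.features_per_layer.items():
            if p < 2:
                raise ConfigurationError(f"layer {name!r} must have >= 2 features")
        if not 0 < self.network_density < 1:
            raise ConfigurationError("network_density must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        lo, hi = self.edge_effect_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("edge_effect_range must satisfy 0 <= low <= high")


@dataclass
class GroundTruth:
    """Latent state of one simulated cohort.

    ``true_network`` maps layer → strictly lower-triangular p × p effect
    matrix (entry [i, j] is the effect of feature j on feature i, j < i).
    ``de_features`` are the directly shifted features per layer;
    ``risk_features`` drive the hazard; ``group_labels`` is per-sample.
    """

    true_network: dict[str, np.ndarray]
    de_features: dict[str, list[str]]
    risk_features: dict[str, list[str]]
    group_labels: np.ndarray
    direct_shifts: dict[str, np.ndarray]

    def total_shifts(self, layer: str) -> np.ndarray:
        """Propagated group mean shift of every feature: (I − B)⁻¹ · s."""
        B = self.true_network[layer]
        s = self.direct_shifts[layer]
        return np.linalg.solve(np.eye(len(s)) - B, s)


def simulate_true_network(
    p: int,
    density: float,
    effect_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a sparse acyclic effect matrix (strictly lower triangular).

    Each ordered pair (j → i, j < i) is an edge with probability
    ``density``; effect magnitudes are Uniform[low, high] with random sign.
    """
    if p < 2:
        raise ConfigurationError("p must be >= 2")
    if not 0 < density < 1:
        raise ConfigurationError("density must be in (0, 1)")
    lo, hi = effect_range
    if lo < 0 or hi < lo:
        raise ConfigurationError("effect_range must satisfy 0 <= low <= high")
    rng = np.random.default_rng(seed)
    mask = np.tril(rng.random((p, p)) < density, k=-1)
    mag = rng.uniform(lo, hi, size=(p, p))
    sign = rng.choice([-1.0, 1.0], size=(p, p))
    return np.where(mask, sign * mag, 0.0)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort plus its ground truth; bit-identical under a seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # survival groups first: they drive DE shifts and hazards
    groups = np.where(rng.random(n) < 0.5, "poor", "good")

    layers: dict[str, ExpressionMatrix] = {}
    networks: dict[str, np.ndarray] = {}
    de_features: dict[str, list[str]] = {}
    risk_features: dict[str, list[str]] = {}
    direct_shifts: dict[str, np.ndarray] = {}
    risk_score = np.zeros(n)

    for layer_name, p in config.features_per_layer.items():
        feature_ids = [f"{layer_name}_{i:04d}" for i in range(p)]
        B = simulate_true_network(
            p, config.network_density, config.edge_effect_range, rng
        )
        n_de = int(round(config.de_fraction * p))
        de_idx = np.sort(rng.choice(p, size=n_de, replace=False))
        shift = np.zeros(p)
        shift[de_idx] = config.de_effect * config.noise_sd

        eps = rng.normal(0.0, config.noise_sd, size=(p, n))
        drive = eps + shift[:, None] * (groups == "poor")[None, :]
        # acyclic recursion g = (I - B)^{-1} drive, solved by forward pass
        G = np.empty((p, n))
        for i in range(p):
            G[i] = drive[i] + B[i, :i] @ G[:i]

        n_risk = min(config.risk_features_per_layer, n_de)
        risk_idx = de_idx[:n_risk] if n_risk else np.array([], dtype=int)
        risk_score += config.risk_weight * G[risk_idx].sum(axis=0)

        layers[layer_name] = ExpressionMatrix(layer_name, feature_ids, sample_ids, G)
        networks[layer_name] = B
        de_features[layer_name] = [feature_ids[i] for i in de_idx]
        risk_features[layer_name] = [feature_ids[i] for i in risk_idx]
        direct_shifts[layer_name] = shift

    # exponential survival with log-hazard linear in the risk features
    risk_score -= risk_score.mean()  # center so baseline_hazard sets the scale
    hazard = config.baseline_hazard * np.exp(np.clip(risk_score, -20, 20))
    true_times = rng.exponential(1.0 / hazard)
    times, events = _administrative_censoring(true_times, config.censor_rate, rng)

    a, b = config.purity_beta_params
    purity = rng.beta(a, b, size=n)

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "time": times,
        "event": events,
        "group": groups,
        "purity": purity,
    })
    cohort = Cohort(layers, clinical)
    truth = GroundTruth(networks, de_features, risk_features, groups, direct_shifts)
    return cohort, truth


def _administrative_censoring(
    true_times: np.ndarray, censor_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0, τ) censoring, τ calibrated so E[censored fraction] ≈ rate."""
    n = len(true_times)
    if censor_rate <= 0:
        return true_times, np.ones(n, dtype=int)
    if censor_rate >= 1:
        c = rng.uniform(0, np.maximum(true_times, 1e-12))
        return c, np.zeros(n, dtype=int)

    def censored_frac(tau: float) -> float:
        # P(C < T | T = t) for C ~ U(0, tau) is min(t/tau, 1)
        return float(np.minimum(true_times / tau, 1.0).mean())

    lo, hi = np.min(true_times) * 1e-3 + 1e-12, np.max(true_times) * 1e3 + 1.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    tau = np.sqrt(lo * hi)
    c = rng.uniform(0, tau, size=n)
    events = (true_times <= c).astype(int)
    times = np.minimum(true_times, c)
    return times, events


def write_cohort(cohort: Cohort, truth: GroundTruth | None, outdir) -> None:
    """Write one TSV per layer, clinical.tsv, and ground-truth edge lists."""
    os.makedirs(outdir, exist_ok=True)
    for name, mat in cohort.layers.items():
        write_expression(mat, os.path.join(outdir, f"{name}.tsv"))
    write_clinical(cohort.clinical, os.path.join(outdir, "clinical.tsv"))
    if truth is None:
        return
    rows = []
    for layer, B in truth.true_network.items():
        ids = cohort.layers[layer].feature_ids
        for i, j in zip(*np.nonzero(B)):
            rows.append((ids[j], ids[i], B[i, j]))
    pd.DataFrame(rows, columns=["regulator", "target", "effect"]).to_csv(
        os.path.join(outdir, "true_edges.tsv"), sep="\t", index=False
    )
    de_rows = [(layer, f) for layer, feats in truth.de_features.items() for f in feats]
    pd.DataFrame(de_rows, columns=["layer", "feature_id"]).to_csv(
        os.path.join(outdir, "true_de_features.tsv"), sep="\t", index=False
    )
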