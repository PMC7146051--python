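"""End-to-end orchestration: cohort → purity filter → DE screen →
signature + CV → group networks → survival stratification → report.

Every stage writes its outputs to files inside the run directory, so a
stage can be inspected or re-run in isolation; a manifest (YAML) records
the effective configuration verbatim plus every artifact written.  A
failing stage aborts with a stage-named error after writing the partial
manifest.  Re-running with an identical configuration reproduces
identical outputs.

Network inference on a full expression layer is quadratic in the feature
count, so the pipeline infers group networks on each layer's strongest DE
features (``network_features`` of them, default 30) — the regime the
per-feature regressions are designed for.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import cohort as cio
from . import network as net
from . import survival as surv
from .cohort import Cohort, purity_filter, read_clinical, read_expression
from .diffexpr import moderated_t, select_de_features, write_de_results
from .prognosis import (DEFAULT_LAYER_SIZES, SignatureConfig, build_signature,
                        cross_validate, write_signature)
from .sparse import RandomLassoConfig
from .synthetic import SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of input_dir / sim present."""

    input_dir: str | None = None
    sim: SimConfig | None = None
    purity_threshold: float = 0.60
    de_alpha: float = 0.05
    de_top_k: int | None = None
    layer_sizes: dict[str, int] | None = None
    network_features: int = 30
    network_layers: list[str] | None = None
    random_lasso: RandomLassoConfig = field(default_factory=RandomLassoConfig)
    k_folds: int = 5
    balance: bool = True
    n_bootstrap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("exactly one of input_dir / sim must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            for key in ("edge_effect_range", "purity_beta_params"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["sim"] = SimConfig(**sim)
        if "random_lasso" in raw and raw["random_lasso"] is not None:
            raw["random_lasso"] = RandomLassoConfig(**raw["random_lasso"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_cohort(config: PipelineConfig, outdir: str) -> Cohort:
    if config.sim is not None:
        cohort, truth = simulate_cohort(config.sim)
        write_cohort(cohort, truth, os.path.join(outdir, "cohort"))
        return cohort
    layers = {}
    for fn in sorted(os.listdir(config.input_dir)):
        if not fn.endswith(".tsv") or fn == "clinical.tsv":
            continue
        if fn in ("true_edges.tsv", "true_de_features.tsv"):
            continue
        path = os.path.join(config.input_dir, fn)
        layers[fn[:-4]] = read_expression(path)
    clinical = read_clinical(os.path.join(config.input_dir, "clinical.tsv"))
    return Cohort(layers, clinical)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written as YAML)."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": []}

    def record(stage: str, *paths: str) -> None:
        manifest["stages"][stage] = "ok"
        manifest["outputs"].extend(paths)
        _write_manifest(manifest, outdir)

    def fail(stage: str, err: Exception) -> None:
        manifest["stages"][stage] = f"failed: {err}"
        _write_manifest(manifest, outdir)
        raise StageError(f"stage {stage!r} failed: {err}") from err

    # ---- cohort ----
    try:
        cohort = _load_cohort(config, outdir)
    except Exception as err:  # noqa: BLE001 — reported with stage name
        fail("cohort", err)
    record("cohort")

    # ---- purity filter ----
    try:
        cohort = purity_filter(cohort, config.purity_threshold)
        if not cohort.sample_ids:
            raise ValueError("no samples retained")
        cio.write_clinical(cohort.clinical,
                           os.path.join(outdir, "clinical_filtered.tsv"))
    except Exception as err:
        fail("purity_filter", err)
    record("purity_filter", "clinical_filtered.tsv")

    # ---- differential expression ----
    de_features: dict[str, list[str]] = {}
    try:
        groups = cohort.group_labels()
        de_paths = []
        for layer, mat in cohort.layers.items():
            res = moderated_t(mat, groups)
            path = os.path.join(outdir, f"de_results_{layer}.tsv")
            write_de_results(res, path)
            de_paths.append(os.path.basename(path))
            de_features[layer] = select_de_features(
                res, alpha=config.de_alpha, top_k=config.de_top_k)
    except Exception as err:
        fail("diffexpr", err)
    record("diffexpr", *de_paths)

    # ---- signature + cross-validation ----
    try:
        sig_cfg = SignatureConfig(
            layer_sizes=dict(config.layer_sizes or DEFAULT_LAYER_SIZES),
            de_alpha=config.de_alpha, de_top_k=config.de_top_k,
            n_bootstrap=config.n_bootstrap, seed=config.seed)
        model = build_signature(cohort, de_features, sig_cfg)
        write_signature(model, os.path.join(outdir, "signature.tsv"))
        report = cross_validate(cohort, sig_cfg, k=config.k_folds,
                                balance=config.balance, seed=config.seed)
        with open(os.path.join(outdir, "cv_report.txt"), "w") as fh:
            fh.write(report.to_text() + "\n")
    except Exception as err:
        fail("signature", err)
    record("signature", "signature.tsv", "cv_report.txt")

    # ---- group-specific networks on the strongest DE features ----
    try:
        layers = config.network_layers or list(cohort.layers)
        net_paths = []
        for layer in layers:
            feats = de_features.get(layer, [])[: config.network_features]
            if len(feats) < 3:
                logger.warning("network stage: layer %s has %d DE features; "
                               "skipped", layer, len(feats))
                continue
            sub = cohort.layers[layer].subset_features(feats)
            cfg = replace(config.random_lasso, seed=config.seed)
            B_T, B_C = net.infer_group_networks(sub, cohort.group_labels(), cfg)
            for adj, tag in ((B_T, "T"), (B_C, "C")):
                path = os.path.join(outdir, f"adjacency_{layer}_{tag}.tsv")
                net.write_adjacency(adj, path)
                net_paths.append(os.path.basename(path))
            edges = net.differential_edges(B_T, B_C, delta_threshold=1e-8)
            epath = os.path.join(outdir, f"edges_{layer}.tsv")
            net.write_edge_list(edges, epath)
            net_paths.append(os.path.basename(epath))
    except Exception as err:
        fail("networks", err)
    record("networks", *net_paths)

    # ---- survival: KM by group and by signature risk score ----
    try:
        clin = cohort.clinical
        times = clin["time"].to_numpy()
        events = clin["event"].to_numpy()
        groups = clin["group"].to_numpy()
        surv_paths = []
        for label in np.unique(groups):
            sel = groups == label
            curve = surv.km_estimate(times[sel], events[sel])
            path = os.path.join(outdir, f"km_group_{label}.tsv")
            surv.write_km_curve(curve, path)
            surv_paths.append(os.path.basename(path))
        chi_grp, p_grp = surv.logrank_test(times, events, groups)

        scores = model.decision_scores(cohort)
        strata = np.where(scores > np.median(scores), "high_risk", "low_risk")
        for label in ("high_risk", "low_risk"):
            sel = strata == label
            curve = surv.km_estimate(times[sel], events[sel])
            path = os.path.join(outdir, f"km_{label}.tsv")
            surv.write_km_curve(curve, path)
            surv_paths.append(os.path.basename(path))
        chi_sig, p_sig = surv.logrank_test(times, events, strata)
        with open(os.path.join(outdir, "survival_tests.tsv"), "w") as fh:
            fh.write("comparison\tchi_square\tp_value\n")
            fh.write(f"good_vs_poor\t{chi_grp:.6g}\t{p_grp:.6g}\n")
            fh.write(f"signature_high_vs_low\t{chi_sig:.6g}\t{p_sig:.6g}\n")
        manifest["logrank"] = {
            "good_vs_poor": {"chi_square": chi_grp, "p_value": p_grp},
            "signature_high_vs_low": {"chi_square": chi_sig, "p_value": p_sig},
        }
    except Exception as err:
        fail("survival", err)
    record("survival", *surv_paths, "survival_tests.tsv")

    manifest["cv"] = {"accuracy": report.accuracy,
                      "error_rate": report.error_rate, "mcc": report.mcc,
                      "best_fold_accuracy": report.best_fold_accuracy}
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir) -> None:
    with open(os.path.join(outdir, "run_manifest.yaml"), "w") as fh:
        yaml.safe_dump(_yaml_safe(manifest), fh, sort_keys=False)


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
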