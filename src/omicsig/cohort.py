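"""Cohort data model: expression matrices, clinical tables, and preprocessing.

A cohort is a set of omics layers (lncRNA, miRNA, mRNA, methylation,
protein — any names are accepted) measured on a shared set of samples,
plus one clinical table carrying survival time, event status, the binary
survival-group label and tumor purity.  All on-disk formats are plain TSV.

Conventions fixed here and used throughout the package:

* **Population SD** (divide by *n*, not *n − 1*) for standardization and
  Z-score flagging.
* Purity filtering removes samples *below* the threshold, so a sample at
  exactly the threshold (e.g. 0.60) is retained.
* Missing expression values are an error, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["sample_id", "time", "event", "group", "purity"]
GROUP_LEVELS = ("good", "poor")


class FormatError(ValueError):
    """Malformed input file or table."""


class ConsistencyError(ValueError):
    """Cross-table inconsistency (e.g. sample missing from clinical)."""


@dataclass
class ExpressionMatrix:
    """One omics layer: a features × samples real matrix with labels."""

    layer_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError(f"{self.layer_name}: values must be 2-D")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise FormatError(
                f"{self.layer_name}: shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features × {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"{self.layer_name}: duplicate {kind} ID {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"{self.layer_name}: non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.layer_name, list(self.feature_ids), list(sample_ids),
            self.values[:, idx].copy(),
        )

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return ExpressionMatrix(
            self.layer_name, list(feature_ids), list(self.sample_ids),
            self.values[idx, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def _first_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class Cohort:
    """All omics layers plus the clinical table, sample-aligned."""

    layers: dict[str, ExpressionMatrix]
    clinical: pd.DataFrame  # columns CLINICAL_COLUMNS, one row per sample

    def __post_init__(self) -> None:
        validate_clinical(self.clinical)
        clin_ids = set(self.clinical["sample_id"])
        for name, mat in self.layers.items():
            missing = [s for s in mat.sample_ids if s not in clin_ids]
            if missing:
                raise ConsistencyError(
                    f"layer {name!r}: samples {missing[:3]} absent from clinical table"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])

    def group_labels(self) -> np.ndarray:
        """Per-sample survival-group labels, aligned with ``sample_ids``."""
        return self.clinical["group"].to_numpy()

    def subset_samples(self, sample_ids: list[str]) -> "Cohort":
        keep = self.clinical["sample_id"].isin(sample_ids)
        clin = self.clinical.loc[keep].reset_index(drop=True)
        order = list(clin["sample_id"])
        layers = {k: v.subset_samples([s for s in order if s in v.sample_ids])
                  for k, v in self.layers.items()}
        return Cohort(layers, clin)


def validate_clinical(df: pd.DataFrame) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing columns {missing}")
    dup = _first_duplicate(list(df["sample_id"]))
    if dup is not None:
        raise FormatError(f"clinical table: duplicate sample ID {dup!r}")
    if (df["time"] < 0).any():
        raise FormatError("clinical table: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("clinical table: event must be 0/1")
    bad = set(df["group"]) - set(GROUP_LEVELS)
    if bad:
        raise FormatError(f"clinical table: unknown group labels {sorted(bad)}")
    if ((df["purity"] < 0) | (df["purity"] > 1)).any():
        raise FormatError("clinical table: purity outside [0, 1]")


# ---------------------------------------------------------------------------
# I/O — TSV, UTF-8, '.' decimal, first expression column header "feature_id"
# ---------------------------------------------------------------------------

def read_expression(path, layer_name: str | None = None) -> ExpressionMatrix:
    """Read one omics layer from TSV (rows features, columns samples)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str},
                     float_precision="round_trip")
    if df.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column header must be 'feature_id'")
    feature_ids = df["feature_id"].tolist()
    sample_ids = list(df.columns[1:])
    body = df.iloc[:, 1:]
    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        if coerced.isna().any() and not body[col].isna().all():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise FormatError(
                f"{path}: non-numeric or missing cell at feature "
                f"{feature_ids[row]!r}, sample {col!r}"
            )
        body[col] = coerced
    name = layer_name if layer_name is not None else _stem(path)
    return ExpressionMatrix(name, feature_ids, sample_ids, body.to_numpy(dtype=float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    validate_clinical(df)
    return df[CLINICAL_COLUMNS]


def write_clinical(df: pd.DataFrame, path) -> None:
    validate_clinical(df)
    df[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def _stem(path) -> str:
    import os
    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def purity_filter(cohort: Cohort, threshold: float = 0.60) -> Cohort:
    """Drop samples whose tumor purity is below ``threshold``.

    Samples at exactly the threshold are retained ("below 60%" are the ones
    removed).  All layers and the clinical table are filtered consistently.
    Idempotent, and the retained set is monotone non-increasing in the
    threshold.
    """
    keep = cohort.clinical.loc[cohort.clinical["purity"] >= threshold, "sample_id"]
    retained = list(keep)
    logger.info("purity_filter: retained %d/%d samples at threshold %.3g",
                len(retained), len(cohort.clinical), threshold)
    return cohort.subset_samples(retained)


def standardize_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each feature to mean 0 and scale to population SD 1.

    Constant features (SD exactly 0) carry no information for regression or
    DE screening; they are dropped and the count is logged.
    """
    vals = matrix.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population SD convention
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("standardize_features(%s): dropped %d constant feature(s)",
                       matrix.layer_name, n_dropped)
    out = (vals[keep] - mean[keep]) / sd[keep]
    return ExpressionMatrix(
        matrix.layer_name,
        [f for f, k in zip(matrix.feature_ids, keep) if k],
        list(matrix.sample_ids),
        out,
    )


def flag_upregulated(matrix: ExpressionMatrix, z_threshold: float = 2.0) -> np.ndarray:
    """Binary per-feature, per-sample up-regulation flags.

    A sample is flagged for a feature when its Z-score — (value − feature
    mean) / feature population SD, computed across all samples of the
    matrix — exceeds ``z_threshold`` (default 2: mean expression over 2 SDs).
    Zero-SD features yield all-zero flags with a warning.
    """
    vals = matrix.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    zero_sd = sd[:, 0] == 0
    if zero_sd.any():
        logger.warning("flag_upregulated(%s): %d zero-SD feature(s), flags set to 0",
                       matrix.layer_name, int(zero_sd.sum()))
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (vals - mean) / safe_sd
    flags = (z > z_threshold).astype(np.int8)
    flags[zero_sd, :] = 0
    return flags
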