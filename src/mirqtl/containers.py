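"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of tabular data around: per-sample variant
dosages with variant metadata, per-feature expression with genomic
coordinates, and flat association/summary tables.  Containers are thin
dataclasses over numpy arrays and pandas frames; they validate their
invariants on construction and expose the few derived views (hard calls,
subsets) the analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
ASSOC_COLUMNS = [
    "variant_id", "chrom", "pos", "feature_id",
    "beta", "se", "stat", "p", "n", "flags",
]
SUMMARY_COLUMNS = ["id", "chrom", "pos", "beta", "se", "z", "p"]


def hard_call(dosages: np.ndarray) -> np.ndarray:
    """Round dosages in [0, 2] to genotype classes {0, 1, 2}.

    Exact half-integer ties (0.5, 1.5) resolve toward the heterozygote:
    genotype-class filters and IBS similarity are defined on classes, and
    the heterozygote is the conservative call for an ambiguous dosage.
    """
    d = np.asarray(dosages, dtype=float)
    out = np.rint(d)
    frac = d - np.floor(d)
    tie = np.isclose(frac, 0.5)
    out = np.where(tie, 1.0, out)
    return np.clip(out, 0.0, 2.0).astype(np.int8)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` holds imputed alternate-allele dosages in [0, 2] with shape
    (n_samples, n_variants).  ``variants`` is a frame with columns
    id/chrom/pos/ref/alt, positionally aligned with the dosage columns.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame
    pool: "object | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample list does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant table does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        if m and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("variant ids not unique")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def hard_calls(self) -> np.ndarray:
        return hard_call(self.dosages)

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if hits.size != 1:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(hits[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)].copy()

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            pool=self.pool,
        )

    def subset_samples(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            pool=self.pool,
        )


@dataclass
class ExpressionMatrix:
    """Features x samples expression with feature coordinates.

    ``values`` is a pandas frame indexed by feature id with sample columns;
    ``features`` carries chrom/start/end/strand per feature (1-based,
    inclusive coordinates).  ``stage`` tracks how far the values have moved
    through the preparation pipeline: raw counts, normalized (variance-
    stabilized), or residualized.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    stage: str = "raw"

    _STAGES = ("raw", "normalized", "residualized")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValueError(f"stage must be one of {self._STAGES}")
        if self.values.index.duplicated().any():
            raise ValueError("feature ids not unique")
        if self.stage == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        extra = self.values.index.difference(self.features.index)
        if len(extra):
            raise ValueError(f"features without coordinates: {list(extra)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, features=self.features, stage=stage)


@dataclass
class KinshipMatrix:
    """Identity-by-state sample similarity, one matrix per excluded chromosome."""

    values: np.ndarray
    samples: list[str]
    excluded_chrom: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over the sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("kinship diagonal must be 1")
        if self.values.min() < -1e-10 or self.values.max() > 1 + 1e-10:
            raise ValueError("kinship entries must lie in [0, 1]")


@dataclass
class VarianceComponents:
    """Null-model variance components Var(y) = sigma_g2 * K + sigma_e2 * I."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2; inf means sigma_g2 == 0
    reml_loglik: float
    boundary: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma_g2 == 0 and self.sigma_e2 == 0 and not self.degenerate:
            raise ValueError("variance components cannot both be zero")


@dataclass
class EqtlRecord:
    """A declared conditionally-independent local eQTL."""

    feature_id: str
    variant_id: str
    degree: int  # 1 = primary, 2 = secondary, ...
    beta: float
    se: float
    p_nominal: float
    p_local_adj: float | None = None
    q_global: float | None = None
    variance_explained_pct: float | None = None
    regime: str = "stringent"


def eqtl_records_frame(records: Sequence[EqtlRecord]) -> pd.DataFrame:
    cols = ["feature_id", "variant_id", "degree", "beta", "se",
            "p_nominal", "p_local_adj", "q_global",
            "variance_explained_pct", "regime"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


@dataclass
class SummaryStats:
    """Per-variant marginal association summary statistics for one trait."""

    table: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns {missing}")
        p = self.table["p"].to_numpy(float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class TruthTable:
    """Planted simulation truth: one row per planted cis signal."""

    table: pd.DataFrame  # feature_id, variant_id, beta, degree, shared_with_gwas

    def __post_init__(self) -> None:
        need = ["feature_id", "variant_id", "beta", "degree", "shared_with_gwas"]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"truth table missing columns {missing}")
        for fid, sub in self.table.groupby("feature_id"):
            degrees = sorted(sub["degree"].tolist())
            if degrees != list(range(1, len(degrees) + 1)):
                raise ValueError(f"degrees for {fid} not consecutive from 1")
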