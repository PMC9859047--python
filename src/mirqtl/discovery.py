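"""Cis-window construction, multiple testing, and conditional discovery.

Multiple-testing correction is hierarchical: the minimum nominal p of each
feature locus is first adjusted locally for the effective number of
independent tests in its window (an eigenvalue decomposition of the
variant correlation matrix), then Benjamini-Hochberg is applied across
feature loci at 5% FDR.  The stringent nominal threshold is the largest
nominal index p among the features that survive; a relaxed regime applies
BH across all tests directly.  Conditionally independent signals are then
discovered per significant feature by stepwise conditioning on previously
found index variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import EqtlRecord, GenotypeMatrix, KinshipMatrix
from .mixedmodel import conditional_design, emma_reml, emmax_scan


@dataclass
class CisWindow:
    """The +/- flank interval around one feature and the variants inside."""

    feature_id: str
    chrom: str
    start: int
    end: int
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start exceeds end")


@dataclass
class ThresholdSet:
    """Nominal significance cutoffs for the two regimes."""

    stringent: float | None
    relaxed: float | None
    fdr: float = 0.05
    m_features: int = 0
    m_tests: int = 0

    def for_regime(self, regime: str) -> float | None:
        if regime not in ("stringent", "relaxed"):
            raise ValueError("regime must be 'stringent' or 'relaxed'")
        return self.stringent if regime == "stringent" else self.relaxed


def define_cis_window(feature_id: str, feature_row: pd.Series,
                      variants: pd.DataFrame,
                      flank: int = 1_000_000) -> CisWindow:
    """Closed interval [start - flank, end + flank], floored at position 1."""
    chrom = feature_row["chrom"]
    start = max(1, int(feature_row["start"]) - flank)
    end = int(feature_row["end"]) + flank
    mask = ((variants["chrom"] == chrom)
            & (variants["pos"] >= start) & (variants["pos"] <= end))
    ids = variants.loc[mask, "id"].tolist()
    if not ids:
        import warnings
        warnings.warn(f"cis window for {feature_id} contains no variants")
    return CisWindow(feature_id=feature_id, chrom=chrom, start=start,
                     end=end, variant_ids=ids)


def effective_tests(dosages: np.ndarray, window_size: int = 200,
                    var_threshold: float = 0.99) -> int:
    """Effective number of independent tests in a variant window.

    Variants (columns, ordered by position) are partitioned into consecutive
    blocks of ``window_size``; per block the eigenvalues of the sample
    correlation matrix are taken and the block's effective count is the
    smallest k whose top-k eigenvalues capture ``var_threshold`` of the
    total.  The window's M_eff is the sum over blocks.
    """
    m = dosages.shape[1]
    if m == 0:
        raise ValueError("empty variant window")
    if np.any(dosages.std(axis=0) == 0):
        raise ValueError("zero-variance variant in window; filter first")
    m_eff = 0
    for lo in range(0, m, window_size):
        block = dosages[:, lo:lo + window_size]
        if block.shape[1] == 1:
            m_eff += 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        vals = np.linalg.eigvalsh(corr)[::-1]
        vals = np.clip(vals, 0.0, None)
        frac = np.cumsum(vals) / vals.sum()
        m_eff += int(np.searchsorted(frac, var_threshold) + 1)
    return m_eff


def eigen_mt(dosages: np.ndarray, p_min: float, window_size: int = 200,
             var_threshold: float = 0.99) -> tuple[float, int]:
    """Locally adjusted minimum p: min(1, M_eff * p_min)."""
    m_eff = effective_tests(dosages, window_size=window_size,
                            var_threshold=var_threshold)
    return min(1.0, m_eff * p_min), m_eff


def hierarchical_fdr(feature_table: pd.DataFrame,
                     fdr: float = 0.05) -> tuple[pd.DataFrame, ThresholdSet]:
    """BH step-up across feature loci on locally adjusted minimum p-values.

    ``feature_table`` needs columns feature_id, p_adj (eigenMT-adjusted
    minimum p) and p_nominal (the nominal p of the index variant).  Returns
    the table with ``q`` and ``significant`` columns, plus a ThresholdSet
    whose stringent cutoff is the largest nominal index p among the
    rejected features.
    """
    if feature_table.empty:
        raise ValueError("no feature loci to adjust")
    reject, q, *_ = multipletests(feature_table["p_adj"].to_numpy(float),
                                  alpha=fdr, method="fdr_bh")
    out = feature_table.copy()
    out["q"] = q
    out["significant"] = reject
    stringent = (float(out.loc[out["significant"], "p_nominal"].max())
                 if reject.any() else None)
    ts = ThresholdSet(stringent=stringent, relaxed=None, fdr=fdr,
                      m_features=len(out))
    return out, ts


def global_fdr(p_values: np.ndarray, fdr: float = 0.05) -> tuple[float | None, int]:
    """Relaxed nominal threshold: largest p whose BH q is <= fdr.

    Returns (threshold, m_tests); the threshold is None when nothing is
    rejected.
    """
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    if not reject.any():
        return None, int(p.size)
    return float(p[reject].max()), int(p.size)


def _argmin_p(scan: pd.DataFrame) -> pd.Series:
    """Row of the minimum valid p; ties break by position then variant id."""
    valid = scan[scan["p"].notna()]
    if valid.empty:
        raise ValueError("no valid association p-values in window")
    pmin = valid["p"].min()
    cand = valid[valid["p"] == pmin].sort_values(["pos", "variant_id"])
    return cand.iloc[0]


def variance_explained(y_residual: np.ndarray, dosage: np.ndarray) -> float:
    """Percent of residualized expression variance explained by one variant:
    100 x squared Pearson correlation."""
    y = np.asarray(y_residual, float)
    g = np.asarray(dosage, float)
    if y.std() == 0 or g.std() == 0:
        raise ValueError("variance explained undefined for constant input")
    r = np.corrcoef(y, g)[0, 1]
    return float(100.0 * r * r)


def stepwise_conditional(
    feature_id: str, window: GenotypeMatrix, y: np.ndarray, W: np.ndarray,
    kinship: KinshipMatrix, threshold: float, regime: str = "stringent",
    max_degree: int = 10,
) -> list[EqtlRecord]:
    """Stepwise conditional eQTL discovery for one significant feature.

    The feature is assumed to have passed the FDR stage, so the first
    (unconditional) scan's minimum-p variant is the primary index.  Each
    subsequent round re-scans the window with all discovered index
    genotypes added to the design and appends the new minimum-p variant
    while its nominal p stays strictly below ``threshold``.  Variance
    components are estimated once under the null and reused (EMMAX).
    """
    records: list[EqtlRecord] = []
    vc = emma_reml(y, W, kinship)
    index_ids: list[str] = []
    index_dosages: list[np.ndarray] = []
    for degree in range(1, max_degree + 1):
        try:
            design = conditional_design(W, index_dosages, index_ids)
        except ValueError:
            break  # rank failure: stop with the partial result
        scan = emmax_scan(y, design, kinship, vc, window, feature_id=feature_id)
        try:
            top = _argmin_p(scan)
        except ValueError:
            break
        if degree > 1 and not (top["p"] < threshold):
            break
        records.append(EqtlRecord(
            feature_id=feature_id, variant_id=top["variant_id"],
            degree=degree, beta=float(top["beta"]), se=float(top["se"]),
            p_nominal=float(top["p"]), regime=regime))
        index_ids.append(top["variant_id"])
        index_dosages.append(window.dosage_of(top["variant_id"]))
    return records
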