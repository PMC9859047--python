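"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 with a per-sample ``DS`` dosage FORMAT field
(``GT`` is accepted as a fallback and converted to 0/1/2).  Expression
counts, covariates, association results, summary statistics and kinship all
travel as plain TSV; feature coordinates as BED6.  Internally every
coordinate is 1-based inclusive (the VCF convention); BED's 0-based
half-open intervals are converted at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import ExpressionMatrix, GenotypeMatrix, KinshipMatrix, SummaryStats


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------- genotypes

def write_vcf(genotypes: GenotypeMatrix, path) -> Path:
    """Write a minimal VCF 4.2 with a DS FORMAT field."""
    path = Path(path)
    chroms = list(dict.fromkeys(genotypes.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mirqtl-simulate\n")
        fh.write("##INFO=<ID=.,Number=0,Type=Flag,Description=\"placeholder\">\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        V = genotypes.variants
        D = genotypes.dosages
        for j in range(genotypes.n_variants):
            row = V.iloc[j]
            ds = "\t".join(_fmt(D[i, j]) for i in range(genotypes.n_samples))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tDS\t{ds}\n")
    return path


def read_genotypes(path, mean_impute_missing: bool = False) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix.

    DS is used where present; otherwise GT is converted to 0/1/2.
    Multi-allelic records are skipped (the skip count is reported on the
    returned matrix as ``n_multiallelic_skipped``).  Missing genotypes are
    an error unless ``mean_impute_missing`` is set, in which case each
    missing entry is replaced by the variant's mean dosage.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    rows = []
    n_multi = 0
    saw_field = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            saw_field = True
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            if gts is None:
                continue
            saw_field = True
            d = np.select([gts == 0, gts == 1, gts == 3],
                          [0.0, 1.0, 2.0], default=np.nan)
        if np.isnan(d).any():
            if not mean_impute_missing:
                raise ValueError(
                    f"missing genotype at {var.ID or var.POS}; pass "
                    "mean_impute_missing=True to mean-impute")
            fill = np.nanmean(d) if np.isfinite(np.nanmean(d)) else 0.0
            d = np.where(np.isnan(d), fill, d)
        cols.append(d)
        rows.append({"id": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0]})
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    if not saw_field:
        raise ValueError("VCF records carry neither DS nor GT")
    gm = GenotypeMatrix(dosages=np.column_stack(cols), samples=samples,
                        variants=pd.DataFrame(rows))
    gm.n_multiallelic_skipped = n_multi
    return gm


# --------------------------------------------------------------- expression

def write_counts(expression: ExpressionMatrix, path) -> Path:
    path = Path(path)
    expression.values.to_csv(path, sep="\t", index_label="feature_id")
    return path


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_bed(features: pd.DataFrame, path) -> Path:
    """Write feature coordinates as BED6 (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for fid, row in features.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                     f"{fid}\t0\t{row.get('strand', '+')}\n")
    return path


def read_bed(path) -> pd.DataFrame:
    """Read BED6 into the internal 1-based inclusive feature table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start0", "end0", "name", "score", "strand"])
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start0"].astype(int) + 1,
        "end": df["end0"].astype(int),
        "strand": df["strand"].fillna("+"),
    })
    out.index = df["name"].astype(str)
    return out


# --------------------------------------------------------------- covariates

def write_covariates(covariates: pd.DataFrame, path) -> Path:
    """Write the covariate table; a comment line declares column types."""
    path = Path(path)
    types = ",".join(
        f"{c}={'factor' if covariates[c].dtype == object else 'numeric'}"
        for c in covariates.columns)
    with open(path, "w") as fh:
        fh.write(f"#coltypes {types}\n")
        covariates.to_csv(fh, sep="\t", index_label="sample_id")
    return path


def read_covariates(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        types = {}
        if first.startswith("#coltypes"):
            for item in first.split(None, 1)[1].strip().split(","):
                k, v = item.split("=")
                types[k] = v
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
    for col, typ in types.items():
        if typ == "factor":
            df[col] = df[col].astype(str)
        else:
            df[col] = df[col].astype(float)
    if df.isna().any().any():
        raise ValueError("covariate table contains missing values")
    return df


# ------------------------------------------------------------ flat tables

def write_summary_stats(summary: SummaryStats, path) -> Path:
    path = Path(path)
    out = summary.table.rename(columns={"id": "variant_id"})
    out.to_csv(path, sep="\t", index=False)
    return path


def read_summary_stats(path, label: str = "") -> SummaryStats:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"variant_id": "id"})
    if "z" not in df.columns:
        df["z"] = df["beta"] / df["se"]
    return SummaryStats(table=df, label=label or Path(path).stem)


def write_kinship(kinship: KinshipMatrix, path) -> Path:
    """Square TSV with sample header; 12 significant digits round-trip."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(kinship.samples) + "\n")
        for i, s in enumerate(kinship.samples):
            vals = "\t".join(f"{v:.12g}" for v in kinship.values[i])
            fh.write(f"{s}\t{vals}\n")
    return path


def read_kinship(path, excluded_chrom: str | None = None) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return KinshipMatrix(values=df.to_numpy(float), samples=list(df.index),
                         excluded_chrom=excluded_chrom)
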