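"""Allele-specific expression of a mature miRNA at a seed-sequence variant.

Small-RNA reads are assigned to the reference- or alternate-allele mature
sequence by exact, forward-strand, zero-mismatch prefix matching (a read
shorter than the mature sequence matches by exact prefix; a longer read
never matches — no soft clipping).  Reads matching neither allele are
unassigned; reads too short to span the discriminating base match both and
are counted as ambiguous.  Heterozygous donors then enter a paired
two-sided t-test comparing the two allele counts within donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AseTestResult:
    t: float
    p: float
    mean_ref: float
    mean_alt: float
    n_donors: int
    transform: str
    exact_tie: bool = False


def _matches(read: str, allele: str) -> bool:
    return len(read) <= len(allele) and allele.startswith(read)


def first_difference(seq_ref: str, seq_alt: str) -> int:
    """0-based position of the first base where the two alleles differ."""
    for i, (a, b) in enumerate(zip(seq_ref, seq_alt)):
        if a != b:
            return i
    raise ValueError("allele sequences are identical")


def assign_allele_reads(reads: list[str], seq_ref: str,
                        seq_alt: str) -> dict[str, int]:
    """Count reads matching each allele sequence.

    Returns ref/alt/ambiguous/unassigned counts; ref + alt + ambiguous +
    unassigned equals the number of input reads.
    """
    seq_ref = seq_ref.strip().upper()
    seq_alt = seq_alt.strip().upper()
    if len(seq_ref) != len(seq_alt):
        raise ValueError("allele sequences must have equal length")
    first_difference(seq_ref, seq_alt)  # raises if identical
    counts = {"ref": 0, "alt": 0, "ambiguous": 0, "unassigned": 0}
    for raw in reads:
        read = raw.strip().upper()
        if not read:
            continue
        hit_ref = _matches(read, seq_ref)
        hit_alt = _matches(read, seq_alt)
        if hit_ref and hit_alt:
            counts["ambiguous"] += 1
        elif hit_ref:
            counts["ref"] += 1
        elif hit_alt:
            counts["alt"] += 1
        else:
            counts["unassigned"] += 1
    return counts


def allele_count_table(reads_by_donor: dict[str, list[str]],
                       donor_genotypes: dict[str, int],
                       seq_ref: str, seq_alt: str) -> pd.DataFrame:
    """Per-donor allele counts plus the donor's hard-call genotype.

    ``donor_genotypes`` maps donor id to the genotype class at the test
    variant (0 hom-ref, 1 het, 2 hom-alt); only heterozygotes enter the
    downstream paired test.
    """
    rows = []
    for donor, reads in reads_by_donor.items():
        c = assign_allele_reads(reads, seq_ref, seq_alt)
        rows.append({"donor": donor, "genotype": donor_genotypes[donor],
                     "ref_count": c["ref"], "alt_count": c["alt"],
                     "ambiguous": c["ambiguous"],
                     "unassigned": c["unassigned"]})
    return pd.DataFrame(rows).set_index("donor")


def paired_allele_test(table: pd.DataFrame,
                       transform: str = "log2p1") -> AseTestResult:
    """Paired two-sided t-test of ref vs alt counts across het donors.

    ``transform`` is ``log2p1`` (log2(count + 1), the default for skewed
    read counts) or ``none`` (raw counts).
    """
    if transform not in ("none", "log2p1"):
        raise ValueError("transform must be 'none' or 'log2p1'")
    het = table[table["genotype"] == 1]
    if len(het) < 2:
        raise ValueError("need at least 2 heterozygous donors")
    ref = het["ref_count"].to_numpy(float)
    alt = het["alt_count"].to_numpy(float)
    if transform == "log2p1":
        ref = np.log2(ref + 1)
        alt = np.log2(alt + 1)
    diffs = ref - alt
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return AseTestResult(t=0.0, p=1.0, mean_ref=float(ref.mean()),
                                 mean_alt=float(alt.mean()),
                                 n_donors=len(het), transform=transform,
                                 exact_tie=True)
        sign = np.sign(diffs.mean())
        return AseTestResult(t=float(sign * np.inf), p=0.0,
                             mean_ref=float(ref.mean()),
                             mean_alt=float(alt.mean()), n_donors=len(het),
                             transform=transform, exact_tie=True)
    t, p = stats.ttest_rel(ref, alt)
    return AseTestResult(t=float(t), p=float(p), mean_ref=float(ref.mean()),
                         mean_alt=float(alt.mean()), n_donors=len(het),
                         transform=transform)


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or plain one-sequence-per-line text."""
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    if lines[0].startswith(">"):
        seqs, cur = [], []
        for ln in lines:
            if ln.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            else:
                cur.append(ln)
        if cur:
            seqs.append("".join(cur))
        return seqs
    return lines
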