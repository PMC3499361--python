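"""Exon-inclusion splicing QTL and allele-specific expression (ASE).

Exon inclusion is quantified as the exon-level qPCR quantity over the
total-gene quantity (percent), batch-residualized and rank-normalized
before regression on haplotype copy number. ASE is estimated from Sanger
chromatogram peak heights at a heterozygous SNP: the cDNA allele odds are
divided by the same individual's genomic-DNA allele odds — heterozygous
gDNA is a built-in 50:50 calibrator, so any multiplicative per-allele
amplification or dye bias common to both templates cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult, _ols_term
from .prep import rank_normal_transform

__all__ = [
    "SpliceQuant",
    "TraceQuant",
    "AseEstimate",
    "inclusion_fraction",
    "splice_qtl",
    "ase_fraction",
    "ase_test",
    "paired_ase_comparison",
]


@dataclass
class SpliceQuant:
    """Paired qPCR quantities (reference-gene normalized) for one sample."""

    sample_id: str
    exposure: str  # "statin" or "sham"
    total_q: float
    exon_q: float
    batch: str

    def __post_init__(self) -> None:
        if self.total_q <= 0 or self.exon_q < 0:
            raise ValueError("qPCR quantities must be positive (exon may be 0)")


@dataclass
class TraceQuant:
    """Sanger peak heights per allele, for cDNA and genomic DNA."""

    sample_id: str
    snp_id: str
    alleles: tuple[str, str]
    cdna_heights: tuple[float, float]
    gdna_heights: tuple[float, float]

    def __post_init__(self) -> None:
        if min(*self.cdna_heights, *self.gdna_heights) < 0:
            raise ValueError("peak heights must be non-negative")
        if max(self.cdna_heights) == 0:
            raise ValueError("no cDNA signal on either allele")
        if max(self.gdna_heights) == 0:
            raise ValueError("no gDNA signal on either allele")


@dataclass
class AseEstimate:
    fraction: float
    monoallelic: bool = False


def inclusion_fraction(q: SpliceQuant) -> float:
    """Percent of transcripts containing the exon: exon_q / total_q x 100.

    Values above 100% are retained (assay noise) — downstream code may
    inspect them, but they are not clipped here.
    """
    return q.exon_q / q.total_q * 100.0


def splice_qtl(
    fractions: np.ndarray | pd.Series,
    batches: np.ndarray | pd.Series,
    copies: np.ndarray | pd.Series,
) -> AssocResult:
    """Batch-residualize inclusion fractions, rank-normalize, regress on
    haplotype copy number (one exposure arm at a time)."""
    frac = np.asarray(fractions, float)
    cp = np.asarray(copies, float)
    bt = np.asarray(batches)
    if frac.size < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(cp).size < 2:
        raise ValueError("haplotype copy count is constant")
    # batch residuals (cell-mean model: subtract each batch's mean)
    resid = frac.copy()
    for b in np.unique(bt):
        mask = bt == b
        resid[mask] -= resid[mask].mean()
    if np.ptp(resid) == 0:
        raise ValueError("inclusion fractions constant after batch adjustment")
    z = rank_normal_transform(resid)
    X = pd.DataFrame({"const": 1.0, "copies": cp})
    return _ols_term(z, X, "copies")


def ase_fraction(t: TraceQuant) -> AseEstimate:
    """Proportion of transcripts from allele A, gDNA-corrected.

    corrected odds = (cA/cB) / (gA/gB); fraction = odds / (1 + odds).
    The gDNA of a heterozygote carries one copy of each allele, so its
    observed odds measure pure assay bias; dividing by them removes any
    per-allele multiplicative bias shared by the two templates.
    """
    cA, cB = t.cdna_heights
    gA, gB = t.gdna_heights
    if gA <= 0 or gB <= 0:
        raise ValueError("both gDNA peak heights must be positive for correction")
    if cB == 0:
        return AseEstimate(fraction=1.0, monoallelic=True)
    if cA == 0:
        return AseEstimate(fraction=0.0, monoallelic=True)
    odds = (cA / cB) / (gA / gB)
    return AseEstimate(fraction=odds / (1.0 + odds))


def ase_test(
    fractions: np.ndarray | list[float], null: float = 0.5
) -> dict:
    """Summarize corrected ASE fractions across heterozygotes and test
    deviation from the balanced null with an exact Wilcoxon signed-rank.

    Returns mean, SE, a normal-approximation 95% CI, and the signed-rank p.
    """
    f = np.asarray(fractions, float)
    if f.size < 3:
        raise ValueError("need at least 3 heterozygous samples")
    mean = float(f.mean())
    se = float(f.std(ddof=1) / np.sqrt(f.size))
    ci = (mean - 1.96 * se, mean + 1.96 * se)
    diffs = f - null
    if np.all(diffs == 0):
        p = 1.0
    else:
        mode = "exact" if f.size <= 25 else "approx"
        p = float(stats.wilcoxon(diffs[diffs != 0], mode=mode).pvalue)
    return {"mean": mean, "se": se, "ci95": ci, "p": p, "n": int(f.size)}


def paired_ase_comparison(
    statin_fractions: np.ndarray | list[float],
    sham_fractions: np.ndarray | list[float],
) -> dict:
    """Descriptive statin-vs-sham ASE comparison (paired signed-rank)."""
    a = np.asarray(statin_fractions, float)
    b = np.asarray(sham_fractions, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 matched statin/sham fraction pairs")
    d = a - b
    if np.all(d == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(a, b).pvalue)
    return {"mean_difference": float(d.mean()), "p": p, "n": int(a.size)}
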