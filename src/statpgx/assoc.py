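"""Lipid-response phenotypes and haplotype association.

The clinical outcome is the delta-log phenotype — log of the mean
on-treatment LDL-cholesterol minus the log of the mean baseline — tested
against haplotype copy number (0/1/2) under an additive genetic model by
ordinary least squares, adjusting for age, sex, BMI, smoking status and
(in combined two-trial analyses) a study indicator. Unadjusted percent
change supports the descriptive group summaries.

The RHOA haplotype table (four common haplotypes over 24 tag SNPs near the
gene, with their counts in the CAP and PRINCE trial populations) is encoded
here and serves both as the default haplotype-definition input and as the
frequency table for cohort simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CohortRecord",
    "HaplotypeDef",
    "AssocResult",
    "RHOA_SNPS",
    "RHOA_HAPLOTYPES",
    "RHOA_HAPLOTYPE_COUNTS",
    "delta_log",
    "percent_change",
    "assign_haplotype_copies",
    "haplotype_assoc",
    "group_summary",
    "haplotype_frequencies",
    "expr_pheno_assoc",
]

#: Tag SNPs (ordered) used to define the four common RHOA haplotypes.
RHOA_SNPS: tuple[str, ...] = (
    "rs6446272", "rs1464569", "rs1464566", "rs1464567", "rs4855873",
    "rs1464568", "rs10640", "rs9814873", "rs6997", "rs6784820",
    "rs6779524", "rs940045", "rs13096474", "rs2140270", "rs6797765",
    "rs4955412", "rs7621003", "rs17595772", "rs11716445", "rs974495",
    "rs3448", "rs3811699", "rs17650792", "rs17080528",
)

#: Allele vectors per haplotype over RHOA_SNPS. H3A and H3B differ only at
#: rs11716445 (C vs T).
RHOA_HAPLOTYPES: dict[str, str] = {
    "H1":  "CCGCGTCTGCGTGTCGGTCGGACG",
    "H2":  "CTAGTCCTGTGCACTTACCAAATG",
    "H3A": "TCAGTCTCATATGTTTACCGGGTA",
    "H3B": "TCAGTCTCATATGTTTACTGGGTA",
}

#: Observed haplotype counts in the two statin trial populations.
RHOA_HAPLOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "H1": {"CAP": 476, "PRINCE": 1154},
    "H2": {"CAP": 311, "PRINCE": 671},
    "H3A": {"CAP": 282, "PRINCE": 576},
    "H3B": {"CAP": 105, "PRINCE": 255},
}

COVARIATE_COLS = ["age", "sex", "bmi", "smoking"]


@dataclass
class HaplotypeDef:
    """A haplotype as an ordered allele vector over named SNPs."""

    hap_id: str
    snp_ids: tuple[str, ...]
    alleles: str

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.snp_ids):
            raise ValueError(
                f"{self.hap_id}: allele vector length {len(self.alleles)} "
                f"!= {len(self.snp_ids)} SNPs"
            )


def default_haplotype_defs() -> list[HaplotypeDef]:
    return [
        HaplotypeDef(h, RHOA_SNPS, a) for h, a in RHOA_HAPLOTYPES.items()
    ]


@dataclass
class CohortRecord:
    """One trial participant: lipid measures, covariates, haplotype copies."""

    subject_id: str
    study: str  # "CAP" or "PRINCE"
    baseline_ldl: list[float]
    on_treatment_ldl: list[float]
    age: float
    sex: int  # 0/1
    bmi: float
    smoking: int  # 0/1
    hap_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.baseline_ldl or not self.on_treatment_ldl:
            raise ValueError("need at least one baseline and one on-treatment measure")
        if min(self.baseline_ldl) <= 0 or min(self.on_treatment_ldl) <= 0:
            raise ValueError("lipid measures must be positive")
        if self.hap_copies and sum(self.hap_copies.values()) != 2:
            raise ValueError("haplotype copies must sum to 2")


@dataclass
class AssocResult:
    """One regression term: effect size, SE, p and sample size."""

    term: str
    beta: float
    se: float
    p: float
    n: int


def delta_log(baseline: list[float], on_treatment: list[float]) -> float:
    """log(mean on-treatment) - log(mean baseline)."""
    mb, mt = float(np.mean(baseline)), float(np.mean(on_treatment))
    if mb <= 0 or mt <= 0:
        raise ValueError("lipid means must be positive")
    return float(np.log(mt) - np.log(mb))


def percent_change(baseline: list[float], on_treatment: list[float]) -> float:
    """(mean on-treatment - mean baseline) / mean baseline x 100."""
    mb, mt = float(np.mean(baseline)), float(np.mean(on_treatment))
    if mb <= 0:
        raise ValueError("baseline mean must be positive")
    return float((mt - mb) / mb * 100.0)


def assign_haplotype_copies(
    chromosomes: tuple[dict[str, str], dict[str, str]] | list[dict[str, str]],
    defs: list[HaplotypeDef] | None = None,
) -> dict[str, int]:
    """Match each phased chromosome to the unique haplotype it equals.

    ``chromosomes`` holds two per-chromosome SNP->allele maps. A chromosome
    matching no definition counts toward ``"other"`` and contributes zero
    copies to every defined haplotype. Definitions must be mutually
    distinguishable over their SNPs.
    """
    defs = defs if defs is not None else default_haplotype_defs()
    if len(chromosomes) != 2:
        raise ValueError("expected exactly two chromosomes")
    copies = {d.hap_id: 0 for d in defs}
    copies["other"] = 0
    for chrom in chromosomes:
        missing = [s for d in defs for s in d.snp_ids if s not in chrom]
        if missing:
            raise ValueError(f"chromosome lacks alleles for SNPs: {sorted(set(missing))[:5]}")
        hits = [
            d.hap_id
            for d in defs
            if all(chrom[s] == a for s, a in zip(d.snp_ids, d.alleles))
        ]
        if len(hits) > 1:
            raise ValueError(f"definitions not distinct: chromosome matches {hits}")
        copies[hits[0] if hits else "other"] += 1
    return copies


def _cohort_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {
            "subject_id": rec.subject_id,
            "study": rec.study,
            "age": rec.age,
            "sex": rec.sex,
            "bmi": rec.bmi,
            "smoking": rec.smoking,
            "delta_log_ldl": delta_log(rec.baseline_ldl, rec.on_treatment_ldl),
            "pct_change_ldl": percent_change(rec.baseline_ldl, rec.on_treatment_ldl),
        }
        for h, c in rec.hap_copies.items():
            row[f"copies_{h}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def _ols_term(
    y: np.ndarray, X: pd.DataFrame, term: str
) -> AssocResult:
    Xn = X.to_numpy(float)
    if np.linalg.matrix_rank(Xn) < Xn.shape[1]:
        culprits = [
            c
            for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy(float))
            == np.linalg.matrix_rank(Xn)
        ]
        raise ValueError(f"collinear covariates: {culprits or list(X.columns)}")
    fit = sm.OLS(y, Xn).fit()
    j = list(X.columns).index(term)
    return AssocResult(
        term=term,
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        p=float(fit.pvalues[j]),
        n=int(len(y)),
    )


def haplotype_assoc(
    cohort: list[CohortRecord],
    hap_id: str,
    phenotype: str = "delta_log_ldl",
) -> AssocResult:
    """Additive-model OLS of the phenotype on haplotype copy number.

    Adjusts for age, sex, BMI and smoking; a study indicator is included
    whenever the cohort spans more than one trial.
    """
    df = _cohort_frame(cohort)
    col = f"copies_{hap_id}"
    if col not in df.columns:
        raise KeyError(f"no copies recorded for haplotype {hap_id!r}")
    if df[col].nunique() < 2:
        raise ValueError(f"haplotype {hap_id!r} copy count is constant in the cohort")
    X = pd.DataFrame({"const": 1.0, "copies": df[col].astype(float)})
    for c in COVARIATE_COLS:
        X[c] = df[c].astype(float)
    if df["study"].nunique() > 1:
        X["study"] = (df["study"] == sorted(df["study"].unique())[1]).astype(float)
    res = _ols_term(df[phenotype].to_numpy(float), X, "copies")
    res.term = f"{hap_id}_copies"
    return res


def group_summary(cohort: list[CohortRecord], hap_id: str) -> pd.DataFrame:
    """Mean +/- SE of unadjusted percent change by haplotype copy stratum.

    The returned frame carries a ``relative_difference_pct`` attribute:
    (mean_0copy - mean_2copy) / mean_0copy x 100, i.e. how much smaller the
    homozygotes' mean response is relative to non-carriers.
    """
    df = _cohort_frame(cohort)
    col = f"copies_{hap_id}"
    if col not in df.columns:
        raise KeyError(f"no copies recorded for haplotype {hap_id!r}")
    rows = []
    for copies, grp in df.groupby(col):
        pct = grp["pct_change_ldl"]
        rows.append(
            {
                "copies": int(copies),
                "n": len(grp),
                "mean_pct_change": pct.mean(),
                "se_pct_change": pct.std(ddof=1) / np.sqrt(len(grp))
                if len(grp) > 1
                else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("copies").sort_index()
    rel = np.nan
    if 0 in out.index and 2 in out.index:
        m0, m2 = out.loc[0, "mean_pct_change"], out.loc[2, "mean_pct_change"]
        if m0 != 0:
            rel = (m0 - m2) / m0 * 100.0
    out.attrs["relative_difference_pct"] = float(rel)
    return out


def haplotype_frequencies(
    counts: dict[str, dict[str, int]] | None = None,
) -> pd.Series:
    """Combined haplotype frequencies (percent) across study populations."""
    counts = counts if counts is not None else RHOA_HAPLOTYPE_COUNTS
    totals = {h: sum(by_study.values()) for h, by_study in counts.items()}
    if any(v < 0 for v in totals.values()):
        raise ValueError("negative haplotype count")
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("all haplotype counts are zero")
    return pd.Series({h: t / grand * 100.0 for h, t in totals.items()}, name="pct")


def expr_pheno_assoc(
    trait: np.ndarray | pd.Series,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
) -> tuple[float, float]:
    """Phenotype ~ expression trait + covariates; returns (p, partial r2).

    Partial r2 for the trait term is t2 / (t2 + residual df).
    """
    y = np.asarray(phenotype, float)
    x = np.asarray(trait, float)
    if covariates.isna().any().any() or np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values in trait, phenotype or covariates")
    X = pd.DataFrame({"const": 1.0, "trait": x}, index=covariates.index)
    for c in covariates.columns:
        X[c] = covariates[c].astype(float)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few complete cases for the model")
    res = _ols_term(y, X, "trait")
    df_resid = len(y) - X.shape[1]
    tstat = res.beta / res.se if res.se > 0 else np.inf
    partial_r2 = float(tstat**2 / (tstat**2 + df_resid)) if np.isfinite(tstat) else 1.0
    return res.p, partial_r2
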