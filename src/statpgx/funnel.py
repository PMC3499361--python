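"""Candidate-gene filter funnel anchored on HMGCR co-response.

Genes are passed through an ordered cascade of filters — expressed in the
LCL panel, detected in reference liver, statin-responsive in hepatoma lines
(FDR), statin-responsive in LCLs (Q), concordant direction of response in
the two systems — and the survivors are ranked by the correlation of their
statin-induced expression change with that of the anchor gene (HMGCR),
under Bonferroni control at the size of the direction-concordant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prep import DeltaMatrix
from .sam import SamResult, call_responsive

__all__ = [
    "FilterReport",
    "FunnelThresholds",
    "concordant_direction",
    "correlate_with_anchor",
    "bonferroni_threshold",
    "run_funnel",
]


@dataclass
class FunnelThresholds:
    """Stage thresholds; strict inequalities apply at every stage."""

    lcl_detect_alpha: float = 0.05
    liver_detect_alpha: float = 0.05
    hepatoma_fdr: float = 0.01
    lcl_q: float = 0.05
    correlation_alpha: float = 0.05  # family-wise, Bonferroni-divided


@dataclass
class FilterReport:
    """Funnel audit trail: ordered stages, per-gene flags, final candidates."""

    stages: pd.DataFrame  # columns: stage, threshold, survivors
    pass_flags: pd.DataFrame  # genes x stages booleans
    candidates: pd.DataFrame  # indexed by gene, sorted by correlation p
    bonferroni_p: float

    def __post_init__(self) -> None:
        surv = self.stages["survivors"].to_numpy()
        if (np.diff(surv) > 0).any():
            raise ValueError("survivor counts must be non-increasing")


def concordant_direction(fc_a: float, fc_b: float) -> bool:
    """True iff both fold changes move strictly the same way from 1."""
    if fc_a <= 0 or fc_b <= 0:
        raise ValueError("fold changes must be positive")
    la, lb = np.log(fc_a), np.log(fc_b)
    return bool(la * lb > 0)


def correlate_with_anchor(
    delta: DeltaMatrix | pd.DataFrame, anchor_gene, test_genes
) -> pd.DataFrame:
    """Pearson r (and two-sided p, t transform, n-2 df) of each test gene's
    delta vector with the anchor's, across subjects."""
    values = delta.values if isinstance(delta, DeltaMatrix) else delta
    if anchor_gene not in values.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in delta matrix")
    test_genes = list(test_genes)
    if anchor_gene in test_genes:
        raise ValueError("anchor gene must be excluded from its own test set")
    n = values.shape[1]
    if n < 4:
        raise ValueError("need at least 4 subjects for anchor correlation")
    anchor = values.loc[anchor_gene].to_numpy(float)
    X = values.loc[test_genes].to_numpy(float)
    ac = anchor - anchor.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ac) / denom
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    return pd.DataFrame({"r": r, "p": p}, index=pd.Index(test_genes, name="gene"))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def _sorted_candidates(corr: pd.DataFrame) -> pd.DataFrame:
    """Ascending p; ties broken by |r| descending, then gene id."""
    key = corr.assign(_absr=-corr["r"].abs(), _gene=corr.index.astype(str))
    return corr.loc[key.sort_values(["p", "_absr", "_gene"]).index]


def run_funnel(
    lcl_detection_p: pd.DataFrame,
    liver_detection_p: pd.DataFrame,
    hepatoma_de: SamResult,
    lcl_de: SamResult,
    hepatoma_fc: pd.DataFrame,
    lcl_fc: pd.DataFrame,
    delta: DeltaMatrix | pd.DataFrame,
    anchor_gene,
    thresholds: FunnelThresholds | None = None,
) -> FilterReport:
    """Run the full candidate-gene funnel and rank survivors by anchor
    correlation.

    Stage order: LCL expression -> liver detection -> hepatoma FDR -> LCL Q
    -> concordant direction -> Bonferroni-controlled anchor correlation,
    with the Bonferroni denominator equal to the survivor count of the
    direction stage. The anchor gene itself rides through the funnel but is
    excluded from the correlation test; it must survive every earlier stage.
    """
    from .prep import detect_expressed

    th = thresholds or FunnelThresholds()
    universe = pd.Index(lcl_detection_p.index)

    stage_sets: list[tuple[str, float, set]] = []
    current: set = set(universe)
    terminated = False

    def push(name: str, threshold: float, survivors: set) -> None:
        nonlocal current, terminated
        if terminated:
            stage_sets.append((name, threshold, set()))
            return
        current = current & survivors
        if not current:
            # an empty stage ends the funnel cleanly: zero candidates
            terminated = True
        elif anchor_gene not in current:
            raise ValueError(
                f"anchor gene {anchor_gene!r} eliminated at stage {name!r}"
            )
        stage_sets.append((name, threshold, set(current)))

    push("expressed_in_lcl", th.lcl_detect_alpha,
         detect_expressed(lcl_detection_p, th.lcl_detect_alpha))
    push("expressed_in_liver", th.liver_detect_alpha,
         detect_expressed(liver_detection_p, th.liver_detect_alpha))
    push("hepatoma_responsive", th.hepatoma_fdr,
         call_responsive(hepatoma_de, th.hepatoma_fdr, "FDR"))
    push("lcl_responsive", th.lcl_q, call_responsive(lcl_de, th.lcl_q, "Q"))

    concordant = {
        g
        for g in current
        if g in hepatoma_fc.index
        and g in lcl_fc.index
        and concordant_direction(
            hepatoma_fc.loc[g, "fold_change"], lcl_fc.loc[g, "fold_change"]
        )
    }
    push("concordant_direction", float("nan"), concordant)

    n_tests = max(len(current) - 1, 1)  # anchor excluded from its own test
    bonf_p = bonferroni_threshold(th.correlation_alpha, n_tests)
    delta_values = delta.values if isinstance(delta, DeltaMatrix) else delta
    if terminated:
        corr = pd.DataFrame(columns=["r", "p"], index=pd.Index([], name="gene"))
        winners: set = set()
    else:
        testable = sorted(
            (g for g in current if g != anchor_gene and g in delta_values.index),
            key=str,
        )
        corr = correlate_with_anchor(delta, anchor_gene, testable)
        winners = set(corr.index[corr["p"] < bonf_p])
    stage_sets.append(("anchor_correlation", bonf_p, winners))

    stages = pd.DataFrame(
        {
            "stage": [s for s, _, _ in stage_sets],
            "threshold": [t for _, t, _ in stage_sets],
            "survivors": [len(g) for _, _, g in stage_sets],
        }
    )
    flags = pd.DataFrame(
        {name: universe.isin(list(genes)) for name, _, genes in stage_sets},
        index=universe,
    )

    cand = _sorted_candidates(corr.loc[sorted(winners, key=str)])
    cand = cand.join(hepatoma_fc.rename(columns=lambda c: f"hepatoma_{c}"), how="left")
    cand = cand.join(lcl_fc.rename(columns=lambda c: f"lcl_{c}"), how="left")
    cand["hepatoma_fdr"] = hepatoma_de.table["q_value"].reindex(cand.index)
    cand["lcl_q"] = lcl_de.table["q_value"].reindex(cand.index)
    cand = _sorted_candidates(cand)

    return FilterReport(
        stages=stages, pass_flags=flags, candidates=cand, bonferroni_p=bonf_p
    )
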