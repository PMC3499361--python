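"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the study design end to end: a paired
statin-vs-sham LCL expression panel with a latent per-pair
"statin-response" factor that loads on HMGCR and a correlated pathway
block, a small paired hepatoma panel, a liver reference detection table, a
two-trial cohort with four haplotypes at the published frequencies and an
attenuated LDL-C response in flagged-haplotype homozygotes, qPCR
total/exon quantities with a per-copy inclusion effect, and Sanger trace
peak heights with allele skew.

The expression model for the statin-minus-sham delta of gene *g* in pair
*s* is

    delta(g, s) = load(g) * F_s + batch(g, b_s) + sum_k h(g, k) * Z_{k,s} + eps

with ``F_s ~ N(1, 1)`` the latent response factor (nonzero mean, so pathway
genes are differentially expressed on average), ``load(g)`` drawn from the
configured loading range for pathway genes (largest for HMGCR) and zero
elsewhere, per-exposure-batch gene shifts, ``n_hidden_factors`` latent
technical factors, and iid Gaussian noise. Off-pathway gene classes —
unexpressed in LCL or liver, hepatoma-only or LCL-only responders,
direction-discordant responders, and concordant-but-uncorrelated
responders — give the downstream filter funnel strictly monotone attrition.
Every injected effect is recorded in the truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ase import SpliceQuant, TraceQuant
from .assoc import CohortRecord
from .prep import PairedExpressionSet

__all__ = ["SimConfig", "SimOutput", "simulate", "simulate_expression",
           "simulate_hepatoma", "simulate_liver_detection", "simulate_cohort",
           "simulate_traces", "simulate_splice", "ANCHOR_GENE"]

ANCHOR_GENE = "HMGCR"
HAPLOTYPE_IDS = ("H1", "H2", "H3A", "H3B")
FLAGGED_HAPLOTYPE = "H3B"


@dataclass
class SimConfig:
    """Generator configuration. Defaults mirror the study design: 480 LCL
    pairs, 7 hepatoma pairs, 120 liver reference arrays, trial cohorts of
    580 + 1,306 subjects, haplotype frequencies 42.6/25.6/22.4/9.4% and
    group mean LDL-C changes of -30.7% (non-carriers) vs -21.8%
    (flagged-haplotype homozygotes)."""

    n_genes: int = 2000
    n_lcl_pairs: int = 480
    n_hepatoma_pairs: int = 7
    n_liver_samples: int = 120
    pathway_size: int = 40
    factor_loading_range: tuple[float, float] = (0.4, 1.0)
    noise_sd: float = 1.0
    batch_effect_sd: float = 0.3
    n_hidden_factors: int = 2
    hap_freqs: tuple[float, float, float, float] = (0.426, 0.256, 0.224, 0.094)
    base_pct_change_mean: float = -30.7
    attenuated_pct_change_mean: float = -21.8
    lipid_cv: float = 0.05
    seed: int = 0

    # composition of the off-pathway gene universe (fractions of n_genes)
    frac_unexpressed_lcl: float = 0.10
    frac_unexpressed_liver: float = 0.10
    frac_hepatoma_only: float = 0.05
    frac_lcl_only: float = 0.05
    frac_discordant: float = 0.03
    frac_concordant_uncorrelated: float = 0.05

    # secondary magnitudes
    hepatoma_effect_scale: float = 1.5
    hepatoma_noise_sd: float = 0.2
    hidden_loading_sd: float = 0.5
    n_exposure_batches: int = 4
    factor_mean: float = 1.0
    factor_sd: float = 1.0

    # cohort
    n_cap: int = 580
    n_prince: int = 1306
    baseline_ldl_mean: float = 140.0
    baseline_ldl_log_sd: float = 0.2
    response_sd_pct: float = 15.7

    # splicing / traces
    n_splice_samples: int = 115
    n_splice_batches: int = 4
    splice_base_pct: float = 1.0
    splice_per_copy_pct: float = 4.0
    splice_noise_pct: float = 0.5
    n_traces: int = 10
    trace_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_lcl_pairs, self.n_hepatoma_pairs,
                  self.n_liver_samples, self.pathway_size)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.pathway_size >= self.n_genes:
            raise ValueError("pathway_size must be smaller than n_genes")
        hf = np.asarray(self.hap_freqs, float)
        if len(hf) != 4 or (hf <= 0).any() or (hf >= 1).any():
            raise ValueError("hap_freqs must be four probabilities in (0, 1)")
        if abs(hf.sum() - 1.0) > 1e-9:
            raise ValueError("hap_freqs must sum to 1")
        lo, hi = self.factor_loading_range
        if not 0 < lo <= hi:
            raise ValueError("factor_loading_range must be a positive interval")
        class_total = (self.frac_unexpressed_lcl + self.frac_unexpressed_liver
                       + self.frac_hepatoma_only + self.frac_lcl_only
                       + self.frac_discordant + self.frac_concordant_uncorrelated)
        if class_total >= 1.0:
            raise ValueError("gene-class fractions leave no null genes")

    def _rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic RNG per generator component."""
        return np.random.default_rng([int(self.seed) % 2**31, stream])


@dataclass
class SimOutput:
    """Everything the pipeline consumes plus the truth used to make it."""

    lcl_expression: PairedExpressionSet
    hepatoma_expression: PairedExpressionSet
    liver_detection: pd.DataFrame
    cohort: list[CohortRecord]
    traces: list[TraceQuant]
    splice: list[SpliceQuant]
    truth: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# gene truth

def _gene_truth(config: SimConfig) -> pd.DataFrame:
    """Assign gene classes, factor loadings and per-arm mean effects."""
    rng = config._rng(0)
    n = config.n_genes
    genes = [ANCHOR_GENE] + [f"G{i:05d}" for i in range(1, n)]
    cls = np.array(["null"] * n, dtype=object)
    cls[: config.pathway_size] = "pathway"

    def take(frac: float, label: str, start: int) -> int:
        k = int(round(frac * n))
        cls[start : start + k] = label
        return start + k

    pos = config.pathway_size
    pos = take(config.frac_concordant_uncorrelated, "concordant_uncorrelated", pos)
    pos = take(config.frac_discordant, "discordant", pos)
    pos = take(config.frac_hepatoma_only, "hepatoma_only", pos)
    pos = take(config.frac_lcl_only, "lcl_only", pos)
    pos = take(config.frac_unexpressed_liver, "unexpressed_liver", pos)
    pos = take(config.frac_unexpressed_lcl, "unexpressed_lcl", pos)

    lo, hi = config.factor_loading_range
    loading = np.zeros(n)
    loading[: config.pathway_size] = rng.uniform(lo, hi, config.pathway_size)
    loading[0] = hi  # anchor carries the largest loading

    sign = rng.choice([-1.0, 1.0], size=n)
    mag = rng.uniform(lo, hi, n)
    lcl_effect = np.zeros(n)
    hep_effect = np.zeros(n)
    for i in range(n):
        c = cls[i]
        if c == "pathway":
            lcl_effect[i] = loading[i] * config.factor_mean
            hep_effect[i] = loading[i] * config.hepatoma_effect_scale
        elif c == "concordant_uncorrelated":
            lcl_effect[i] = sign[i] * mag[i]
            hep_effect[i] = sign[i] * mag[i] * config.hepatoma_effect_scale
        elif c == "discordant":
            lcl_effect[i] = sign[i] * mag[i]
            hep_effect[i] = -sign[i] * mag[i] * config.hepatoma_effect_scale
        elif c == "hepatoma_only":
            hep_effect[i] = sign[i] * mag[i] * config.hepatoma_effect_scale
        elif c == "lcl_only":
            lcl_effect[i] = sign[i] * mag[i]

    return pd.DataFrame(
        {
            "gene": genes,
            "gene_class": cls,
            "loading": loading,
            "lcl_mean_delta": lcl_effect,
            "hepatoma_mean_delta": hep_effect,
            "expressed_lcl": cls != "unexpressed_lcl",
            "expressed_liver": ~np.isin(cls, ["unexpressed_liver", "unexpressed_lcl"]),
        }
    ).set_index("gene")


def _detection_matrix(
    rng: np.random.Generator, genes: pd.Index, expressed: np.ndarray,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Per-gene, per-sample detection p-values: near 0 when expressed."""
    n_g, n_s = len(genes), len(sample_ids)
    p = np.where(
        expressed[:, None],
        rng.uniform(0.0, 0.05, (n_g, n_s)),
        rng.uniform(0.2, 1.0, (n_g, n_s)),
    )
    return pd.DataFrame(p, index=genes, columns=sample_ids)


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    config: SimConfig, truth: pd.DataFrame | None = None
) -> tuple[PairedExpressionSet, pd.DataFrame]:
    """Paired LCL statin/sham expression with the latent response factor.

    Returns the expression set and the per-gene/per-pair truth. Statin
    intensities are sham plus the generated delta on the log2 scale.
    """
    truth = truth if truth is not None else _gene_truth(config)
    rng = config._rng(1)
    n_g, n_p = config.n_genes, config.n_lcl_pairs
    genes = truth.index

    baseline = rng.normal(8.0, 1.5, n_g)
    factor = rng.normal(config.factor_mean, config.factor_sd, n_p)
    loading = truth["loading"].to_numpy()
    fixed_effect = truth["lcl_mean_delta"].to_numpy() - loading * config.factor_mean
    # fixed_effect covers non-pathway responders (loading 0, nonzero mean)

    exposure_batch = rng.integers(0, config.n_exposure_batches, n_p)
    batch_shift = rng.normal(0.0, config.batch_effect_sd,
                             (n_g, config.n_exposure_batches))
    if config.n_exposure_batches > 1:
        # deviations, not offsets: a gene's batch effects sum to zero, so
        # the batch average is not confounded with its exposure effect
        batch_shift -= batch_shift.mean(axis=1, keepdims=True)
    hidden_load = rng.normal(0.0, config.hidden_loading_sd,
                             (n_g, config.n_hidden_factors)) if config.n_hidden_factors else np.zeros((n_g, 0))
    hidden_score = rng.normal(0.0, 1.0, (config.n_hidden_factors, n_p)) if config.n_hidden_factors else np.zeros((0, n_p))

    eps = rng.normal(0.0, config.noise_sd, (n_g, n_p)) if config.noise_sd > 0 else np.zeros((n_g, n_p))
    delta = (
        loading[:, None] * factor[None, :]
        + fixed_effect[:, None]
        + batch_shift[:, exposure_batch]
        + hidden_load @ hidden_score
        + eps
    )

    sham_noise = rng.normal(0.0, config.noise_sd, (n_g, n_p)) if config.noise_sd > 0 else np.zeros((n_g, n_p))
    sham = baseline[:, None] + sham_noise
    statin = sham + delta

    subjects = [f"S{i:04d}" for i in range(n_p)]
    statin_ids = [f"{s}_statin" for s in subjects]
    sham_ids = [f"{s}_sham" for s in subjects]
    intensities = pd.DataFrame(
        np.hstack([statin, sham]), index=genes, columns=statin_ids + sham_ids
    )
    pairing = pd.DataFrame(
        {
            "subject": subjects * 2,
            "exposure": ["statin"] * n_p + ["sham"] * n_p,
        },
        index=statin_ids + sham_ids,
    )
    age = rng.uniform(25.0, 70.0, n_p)
    sex = rng.integers(0, 2, n_p)
    growth = rng.normal(1.0, 0.15, n_p)
    labeling_batch = rng.integers(0, 3, n_p)
    covariates = pd.DataFrame(
        {
            "age": np.tile(age, 2),
            "sex": np.tile(sex, 2).astype(float),
            "growth_rate": np.tile(growth, 2),
            "exposure_batch": [f"EB{b}" for b in np.tile(exposure_batch, 2)],
            "labeling_batch": [f"LB{b}" for b in np.tile(labeling_batch, 2)],
        },
        index=statin_ids + sham_ids,
    )
    detection = _detection_matrix(
        config._rng(2), genes, truth["expressed_lcl"].to_numpy(), statin_ids + sham_ids
    )
    expr = PairedExpressionSet(
        intensities=intensities, detection_p=detection,
        pairing=pairing, covariates=covariates,
    )
    pair_truth = pd.DataFrame({"subject": subjects, "factor": factor,
                               "exposure_batch": exposure_batch})
    return expr, pair_truth


def simulate_hepatoma(
    config: SimConfig, truth: pd.DataFrame | None = None
) -> PairedExpressionSet:
    """Small paired hepatoma panel; low-noise, larger responsive effects."""
    truth = truth if truth is not None else _gene_truth(config)
    rng = config._rng(3)
    n_g, n_p = config.n_genes, config.n_hepatoma_pairs
    genes = truth.index
    baseline = rng.normal(8.0, 1.5, n_g)
    effect = truth["hepatoma_mean_delta"].to_numpy()
    noise = config.hepatoma_noise_sd
    delta = effect[:, None] + (rng.normal(0.0, noise, (n_g, n_p)) if noise > 0 else 0.0)
    sham = baseline[:, None] + (rng.normal(0.0, noise, (n_g, n_p)) if noise > 0 else 0.0)
    statin = sham + delta
    lines = [f"HEP{i}" for i in range(n_p)]
    statin_ids = [f"{s}_statin" for s in lines]
    sham_ids = [f"{s}_sham" for s in lines]
    intensities = pd.DataFrame(np.hstack([statin, sham]), index=genes,
                               columns=statin_ids + sham_ids)
    pairing = pd.DataFrame(
        {"subject": lines * 2, "exposure": ["statin"] * n_p + ["sham"] * n_p},
        index=statin_ids + sham_ids,
    )
    detection = _detection_matrix(
        config._rng(4), genes, np.ones(n_g, bool), statin_ids + sham_ids
    )
    return PairedExpressionSet(
        intensities=intensities, detection_p=detection, pairing=pairing,
        covariates=pd.DataFrame(index=statin_ids + sham_ids),
    )


def simulate_liver_detection(
    config: SimConfig, truth: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Liver reference: per-gene detection p-values over replicate arrays."""
    truth = truth if truth is not None else _gene_truth(config)
    samples = [f"LIVER{i:03d}" for i in range(config.n_liver_samples)]
    return _detection_matrix(
        config._rng(5), truth.index, truth["expressed_liver"].to_numpy(), samples
    )


# ---------------------------------------------------------------------------
# cohort

def simulate_cohort(config: SimConfig) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Two-trial cohort under Hardy-Weinberg haplotype draws.

    Expected percent LDL-C change is ``base_pct_change_mean`` for
    non-carriers of the flagged haplotype, ``attenuated_pct_change_mean``
    for homozygotes, interpolated additively for heterozygotes, with
    between-subject scatter ``response_sd_pct`` and per-measurement
    multiplicative noise ``lipid_cv``. Two baseline and two on-treatment
    measurements per subject.
    """
    rng = config._rng(6)
    n = config.n_cap + config.n_prince
    studies = ["CAP"] * config.n_cap + ["PRINCE"] * config.n_prince
    freqs = np.asarray(config.hap_freqs, float)
    chrom = rng.choice(len(HAPLOTYPE_IDS), size=(n, 2), p=freqs)
    per_copy = (config.attenuated_pct_change_mean - config.base_pct_change_mean) / 2.0

    records: list[CohortRecord] = []
    truth_rows = []
    for i in range(n):
        copies = {h: int((chrom[i] == j).sum()) for j, h in enumerate(HAPLOTYPE_IDS)}
        c_flag = copies[FLAGGED_HAPLOTYPE]
        expected_pct = config.base_pct_change_mean + per_copy * c_flag
        pct = expected_pct + (rng.normal(0.0, config.response_sd_pct)
                              if config.response_sd_pct > 0 else 0.0)
        pct = max(pct, -95.0)  # keep on-treatment lipids positive
        true_base = config.baseline_ldl_mean * (
            np.exp(rng.normal(0.0, config.baseline_ldl_log_sd))
            if config.baseline_ldl_log_sd > 0 else 1.0
        )
        true_on = true_base * (1.0 + pct / 100.0)

        def measure(level: float, k: int = 2) -> list[float]:
            if config.lipid_cv <= 0:
                return [float(level)] * k
            return [float(level * np.exp(rng.normal(0.0, config.lipid_cv)))
                    for _ in range(k)]

        rec = CohortRecord(
            subject_id=f"P{i:05d}",
            study=studies[i],
            baseline_ldl=measure(true_base),
            on_treatment_ldl=measure(true_on),
            age=float(rng.uniform(35.0, 75.0)),
            sex=int(rng.integers(0, 2)),
            bmi=float(rng.normal(27.0, 4.0)),
            smoking=int(rng.random() < 0.25),
            hap_copies=copies,
        )
        records.append(rec)
        truth_rows.append(
            {"subject_id": rec.subject_id, "study": rec.study,
             "flagged_copies": c_flag, "expected_pct_change": expected_pct,
             "true_pct_change": pct, "true_baseline": true_base}
        )
    return records, pd.DataFrame(truth_rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# traces and splicing

def simulate_traces(
    config: SimConfig, true_allele_fraction: float,
    snp_id: str = "rs11716445", alleles: tuple[str, str] = ("T", "C"),
) -> list[TraceQuant]:
    """Sanger peak heights for heterozygotes at a given true cDNA allele
    fraction; gDNA heights are balanced up to the same multiplicative noise."""
    f = float(true_allele_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("true_allele_fraction must lie in [0, 1]")
    rng = config._rng(7)
    total = 1000.0
    out = []
    for i in range(config.n_traces):
        def noisy(x: float) -> float:
            if config.trace_noise_sd <= 0:
                return x
            return float(x * np.exp(rng.normal(0.0, config.trace_noise_sd)))

        out.append(
            TraceQuant(
                sample_id=f"T{i:03d}",
                snp_id=snp_id,
                alleles=alleles,
                cdna_heights=(noisy(total * f), noisy(total * (1.0 - f))),
                gdna_heights=(noisy(total * 0.5), noisy(total * 0.5)),
            )
        )
    return out


def simulate_splice(config: SimConfig) -> tuple[list[SpliceQuant], pd.DataFrame]:
    """qPCR total/exon quantities with a per-copy exon-inclusion effect.

    Each subject contributes a statin and a sham sample; inclusion percent
    is ``splice_base_pct`` plus ``splice_per_copy_pct`` per flagged-haplotype
    copy, batch shifts, and additive noise (floored just above zero).
    """
    rng = config._rng(8)
    n = config.n_splice_samples
    freqs = np.asarray(config.hap_freqs, float)
    flagged_idx = HAPLOTYPE_IDS.index(FLAGGED_HAPLOTYPE)
    copies = (rng.choice(len(HAPLOTYPE_IDS), size=(n, 2), p=freqs) == flagged_idx).sum(axis=1)
    batches = rng.integers(0, config.n_splice_batches, n)
    batch_shift = rng.normal(0.0, 0.3, config.n_splice_batches)
    out: list[SpliceQuant] = []
    rows = []
    for i in range(n):
        for exposure in ("statin", "sham"):
            total = float(np.exp(rng.normal(0.0, 0.3)))
            incl = (config.splice_base_pct
                    + config.splice_per_copy_pct * copies[i]
                    + batch_shift[batches[i]]
                    + rng.normal(0.0, config.splice_noise_pct))
            incl = max(incl, 0.05)
            out.append(
                SpliceQuant(
                    sample_id=f"SP{i:03d}_{exposure}",
                    exposure=exposure,
                    total_q=total,
                    exon_q=total * incl / 100.0,
                    batch=f"B{batches[i]}",
                )
            )
            rows.append({"sample_id": f"SP{i:03d}_{exposure}", "subject": f"SP{i:03d}",
                         "exposure": exposure, "flagged_copies": int(copies[i]),
                         "true_inclusion_pct": incl, "batch": f"B{batches[i]}"})
    return out, pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------

def simulate(config: SimConfig, true_allele_fraction: float = 0.9) -> SimOutput:
    """Generate the full study: every pipeline input plus truth tables."""
    gene_truth = _gene_truth(config)
    lcl, pair_truth = simulate_expression(config, gene_truth)
    hepatoma = simulate_hepatoma(config, gene_truth)
    liver = simulate_liver_detection(config, gene_truth)
    cohort, cohort_truth = simulate_cohort(config)
    traces = simulate_traces(config, true_allele_fraction)
    splice, splice_truth = simulate_splice(config)
    return SimOutput(
        lcl_expression=lcl,
        hepatoma_expression=hepatoma,
        liver_detection=liver,
        cohort=cohort,
        traces=traces,
        splice=splice,
        truth={
            "genes": gene_truth,
            "lcl_pairs": pair_truth,
            "cohort": cohort_truth,
            "splice": splice_truth,
        },
    )
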