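"""Expression preprocessing: detection filtering, covariate adjustment,
hidden-factor removal, and per-gene rank-based normalization.

The pipeline mirrors common practice for in-vitro drug-exposure expression
panels: each gene's trait is residualized on known sample covariates
(separately within the statin and sham arms, so the exposure effect itself
is never absorbed), principal components explaining more than a configurable
fraction of dataset variance are regressed out as surrogates for unknown
technical factors, and each gene is mapped to normal quantiles so downstream
linear models see Gaussian traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedExpressionSet",
    "DeltaMatrix",
    "detect_expressed",
    "adjust_known_covariates",
    "remove_hidden_factors",
    "rank_normal_transform",
    "make_delta",
]

STATIN = "statin"
SHAM = "sham"


@dataclass
class PairedExpressionSet:
    """Gene x sample log-scale intensities for matched statin/sham exposures.

    Attributes
    ----------
    intensities : DataFrame, genes x samples, log-scale arbitrary units.
    detection_p : DataFrame, genes x samples, detection p-values in [0, 1].
    pairing : DataFrame indexed by sample id with columns ``subject`` and
        ``exposure`` (``"statin"`` or ``"sham"``).
    covariates : DataFrame indexed by sample id (age, sex, batches, growth
        rate, ...). Categorical columns are one-hot encoded at fit time.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    pairing: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.intensities.isna().any().any():
            raise ValueError("intensities contain missing values")
        if not self.detection_p.empty:
            dp = self.detection_p.to_numpy()
            if (dp < 0).any() or (dp > 1).any():
                raise ValueError("detection p-values must lie in [0, 1]")
        if not {"subject", "exposure"}.issubset(self.pairing.columns):
            raise ValueError("pairing needs 'subject' and 'exposure' columns")
        bad = set(self.pairing["exposure"]) - {STATIN, SHAM}
        if bad:
            raise ValueError(f"unknown exposure labels: {sorted(bad)}")
        counts = self.pairing.groupby("subject")["exposure"].agg(
            lambda e: (sum(e == STATIN), sum(e == SHAM))
        )
        unpaired = [s for s, c in counts.items() if c != (1, 1)]
        if unpaired:
            raise ValueError(
                f"subjects without exactly one statin and one sham sample: {unpaired[:5]}"
            )

    @property
    def subjects(self) -> list:
        return sorted(self.pairing["subject"].unique().tolist(), key=str)

    def arm_samples(self, exposure: str) -> pd.Index:
        """Sample ids of one exposure arm, ordered by subject id."""
        arm = self.pairing[self.pairing["exposure"] == exposure]
        by_subject = arm.reset_index().set_index("subject").iloc[:, 0]
        return pd.Index([by_subject[s] for s in self.subjects])


@dataclass
class DeltaMatrix:
    """Gene x subject matrix of statin-minus-sham differences.

    ``values`` holds adjusted, per-gene normalized deltas (one column per
    subject); ``degenerate_genes`` lists genes whose raw deltas were all
    tied and therefore dropped rather than normalized.
    """

    values: pd.DataFrame
    degenerate_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("delta matrix contains non-finite values")


def detect_expressed(detection_p: pd.DataFrame, alpha: float = 0.05) -> set:
    """Genes whose mean detection p-value across all samples is < alpha.

    The strict inequality is deliberate: a gene sitting exactly at the
    detection level is not called expressed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if detection_p.empty:
        raise ValueError("empty detection matrix")
    mean_p = detection_p.mean(axis=1)
    return set(mean_p.index[mean_p < alpha])


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categoricals and prepend an intercept."""
    num = covariates.select_dtypes(include=[np.number])
    cat = covariates.drop(columns=num.columns)
    parts = [pd.DataFrame({"const": 1.0}, index=covariates.index)]
    if not num.empty:
        parts.append(num.astype(float))
    if not cat.empty:
        parts.append(pd.get_dummies(cat.astype(str), drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        culprits = []
        for col in design.columns:
            if col == "const":
                continue
            sub = design.drop(columns=[col]).to_numpy(float)
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise ValueError(
            f"rank-deficient covariate design; collinear columns: {culprits or list(design.columns)}"
        )


def adjust_known_covariates(
    expr: PairedExpressionSet, keep_arm_means: bool = False
) -> PairedExpressionSet:
    """Residualize each gene on the known covariates, per exposure arm.

    Categorical covariates are one-hot encoded; an intercept is always
    included, so residuals are mean-zero within each arm. Fitting within arm
    keeps the statin-vs-sham contrast out of the adjustment.

    With ``keep_arm_means=True`` each gene's within-arm mean is restored
    after residualization, so covariate-linked variation (batch shifts,
    growth-rate trends) is removed but the exposure main effect — the
    quantity paired differential expression tests — survives.
    """
    if expr.covariates.empty:
        raise ValueError("no covariates to adjust for")
    if expr.covariates.isna().any().any():
        raise ValueError("covariate table has missing entries")
    adjusted = expr.intensities.copy().astype(float)
    for exposure in (STATIN, SHAM):
        samples = expr.pairing.index[expr.pairing["exposure"] == exposure]
        design = _design_matrix(expr.covariates.loc[samples])
        _check_full_rank(design)
        X = design.to_numpy(float)
        Y = expr.intensities[samples].to_numpy(float).T  # samples x genes
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        if keep_arm_means:
            resid = resid + Y.mean(axis=0, keepdims=True)
        adjusted[samples] = resid.T
    return replace(expr, intensities=adjusted)


def remove_hidden_factors(
    matrix: pd.DataFrame,
    var_threshold: float = 0.05,
    keep_gene_means: bool = False,
) -> pd.DataFrame:
    """Regress out principal components explaining > var_threshold variance.

    PCs are computed over samples from the per-gene centered matrix; every
    gene is residualized on all components whose variance fraction exceeds
    the threshold. If none do, the (centered) input is returned unchanged.
    With ``keep_gene_means=True`` each gene's mean is restored afterwards,
    minus the part of the means explained (across genes) by the removed
    components' gene loadings: a latent factor with a nonzero sample
    average shifts gene means in proportion to its loadings, and that
    confounded share must go with the factor, while the loading-orthogonal
    share — the genuine per-gene location signal — is preserved.
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must lie in (0, 1]")
    X = matrix.to_numpy(float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    gene_means = X.mean(axis=1, keepdims=True)
    Xc = X - gene_means
    # SVD of the centered gene x sample matrix; right singular vectors are
    # the sample-space components, singular values give variance fractions.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    keep = var_frac > var_threshold
    offset = gene_means if keep_gene_means else 0.0
    if not keep.any():
        return pd.DataFrame(Xc + offset, index=matrix.index, columns=matrix.columns)
    if keep.sum() >= n_samples:
        raise ValueError("cannot remove as many components as there are samples")
    V = Vt[keep].T  # samples x k, orthonormal
    resid = Xc - (Xc @ V) @ V.T
    if keep_gene_means:
        loadings = U[:, keep] * s[keep]  # genes x k
        A = np.hstack([np.ones((n_genes, 1)), loadings])
        beta, *_ = np.linalg.lstsq(A, gene_means, rcond=None)
        offset = gene_means - loadings @ beta[1:]
    return pd.DataFrame(resid + offset, index=matrix.index, columns=matrix.columns)


def rank_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - 0.5) / n).

    Ties get average ranks; the map is monotone, so ordering is preserved.
    Raises on all-tied input (no ordering information to normalize).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if arr.size < 3:
        raise ValueError("need at least 3 values to rank-normalize")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values")
    if np.ptp(arr) == 0:
        raise ValueError("all values identical; nothing to normalize")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.5) / arr.size)


def make_delta(expr: PairedExpressionSet, normalize: bool = True) -> DeltaMatrix:
    """Per-subject statin-minus-sham differences, rank-normalized per gene.

    With ``normalize=False`` the raw (adjusted) differences are returned —
    the form the paired differential-expression statistic consumes; the
    normalized form feeds correlation and association testing. Genes whose
    raw deltas are all tied (typically all-zero) cannot be normalized; they
    are dropped and reported in ``degenerate_genes``.
    """
    subjects = expr.subjects
    if len(subjects) < 3:
        raise ValueError("need at least 3 subject pairs to build deltas")
    statin_cols = expr.arm_samples(STATIN)
    sham_cols = expr.arm_samples(SHAM)
    raw = (
        expr.intensities[statin_cols].to_numpy(float)
        - expr.intensities[sham_cols].to_numpy(float)
    )
    degenerate = [g for g, row in zip(expr.intensities.index, raw) if np.ptp(row) == 0]
    keep_mask = np.array([np.ptp(row) > 0 for row in raw])
    kept = raw[keep_mask]
    if normalize:
        kept = (
            np.vstack([rank_normal_transform(row) for row in kept])
            if keep_mask.any()
            else np.empty((0, len(subjects)))
        )
    values = pd.DataFrame(
        kept, index=expr.intensities.index[keep_mask], columns=subjects
    )
    return DeltaMatrix(values=values, degenerate_genes=degenerate)
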