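"""Probe filtering, beta/M transformation, and covariate residualization.

The M-value M = log2(beta / (1 - beta)) is the analysis scale for linear
modelling: it is unbounded and roughly homoscedastic where beta is
compressed near 0 and 1. Betas are clipped to [eps, 1-eps] before the
transform so boundary values stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnnotationTable, BetaMatrix, ValidationError

DEFAULT_EPSILON = 1e-3


@dataclass
class MMatrix:
    """Probe x sample M-values sharing shape and ordering with the source BetaMatrix."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    epsilon: float = DEFAULT_EPSILON

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterReport:
    """Tally of probes removed per reason, with disjoint precedence
    detection -> SNP -> non-CpG -> sex chromosomes."""

    n_input: int
    n_removed_detection: int
    n_removed_snp: int
    n_removed_noncpg: int
    n_removed_sex_chrom: int
    n_retained: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total_removed = (
            self.n_removed_detection
            + self.n_removed_snp
            + self.n_removed_noncpg
            + self.n_removed_sex_chrom
        )
        assert self.n_input - total_removed == self.n_retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["input", "detection", "snp", "non_cpg", "sex_chromosome", "retained"],
                "n": [
                    self.n_input,
                    self.n_removed_detection,
                    self.n_removed_snp,
                    self.n_removed_noncpg,
                    self.n_removed_sex_chrom,
                    self.n_retained,
                ],
            }
        )


def filter_probes(
    beta: BetaMatrix,
    annotation: AnnotationTable,
    detection_p: pd.DataFrame | None = None,
    keep_sex_chrom: bool = False,
    detection_alpha: float = 0.05,
    max_failed_fraction: float = 0.0,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove unreliable and uninformative probes before modelling.

    Removal reasons, applied in order so the report counts are disjoint:

    1. detection: probes whose fraction of samples with detection
       p > ``detection_alpha`` exceeds ``max_failed_fraction`` (default:
       any failing sample removes the probe);
    2. SNP-overlapping probes (``snp_flag``);
    3. non-CpG control probes (``cpg_probe`` False);
    4. chrX/chrY probes, unless ``keep_sex_chrom`` (the X-chromosome
       analysis path needs them retained).
    """
    missing = [p for p in beta.probe_ids if p not in annotation.probe_ids]
    if missing:
        raise ValidationError(f"annotation does not cover probes: {missing[:10]}")
    ann = annotation.table.loc[beta.probe_ids]

    removed: dict[str, list[str]] = {}
    remaining = pd.Series(True, index=beta.probe_ids)

    if detection_p is not None:
        if list(detection_p.index) != list(beta.probe_ids) or list(detection_p.columns) != list(beta.samples):
            raise ValidationError("detection p-value matrix shape/labels mismatch with beta matrix")
        failed_frac = (detection_p.to_numpy() > detection_alpha).mean(axis=1)
        det_mask = pd.Series(failed_frac > max_failed_fraction, index=beta.probe_ids)
    else:
        det_mask = pd.Series(False, index=beta.probe_ids)
    removed["detection"] = list(beta.probe_ids[det_mask & remaining])
    remaining &= ~det_mask

    snp_mask = ann["snp_flag"] & remaining
    removed["snp"] = list(beta.probe_ids[snp_mask])
    remaining &= ~ann["snp_flag"]

    noncpg_mask = (~ann["cpg_probe"]) & remaining
    removed["non_cpg"] = list(beta.probe_ids[noncpg_mask])
    remaining &= ann["cpg_probe"]

    if keep_sex_chrom:
        removed["sex_chromosome"] = []
    else:
        sex_mask = ann["chromosome"].isin(["chrX", "chrY"]) & remaining
        removed["sex_chromosome"] = list(beta.probe_ids[sex_mask])
        remaining &= ~ann["chromosome"].isin(["chrX", "chrY"])

    kept = list(beta.probe_ids[remaining])
    report = FilterReport(
        n_input=beta.n_probes,
        n_removed_detection=len(removed["detection"]),
        n_removed_snp=len(removed["snp"]),
        n_removed_noncpg=len(removed["non_cpg"]),
        n_removed_sex_chrom=len(removed["sex_chromosome"]),
        n_retained=len(kept),
        removed=removed,
    )
    return beta.subset_probes(kept), report


def beta_to_m(beta: BetaMatrix | pd.DataFrame | np.ndarray, epsilon: float = DEFAULT_EPSILON):
    """M = log2(beta' / (1 - beta')) with beta' clipped to [eps, 1-eps].

    Accepts a BetaMatrix (returns an MMatrix) or a bare array/frame
    (returns the same type).
    """
    if not 0 < epsilon < 0.5:
        raise ValidationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    if isinstance(beta, BetaMatrix):
        clipped = beta.values.clip(lower=epsilon, upper=1 - epsilon)
        m = np.log2(clipped / (1 - clipped))
        return MMatrix(values=m, metadata=beta.metadata.copy(), epsilon=epsilon)
    arr = np.clip(np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta, epsilon, 1 - epsilon)
    return np.log2(arr / (1 - arr))


def m_to_beta(m, epsilon: float = DEFAULT_EPSILON):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    if isinstance(m, MMatrix):
        vals = m.values
        return pd.DataFrame(2.0**vals / (2.0**vals + 1), index=vals.index, columns=vals.columns)
    arr = np.asarray(m, dtype=float) if not isinstance(m, pd.DataFrame) else m
    return 2.0**arr / (2.0**arr + 1)


def residualize_covariates(m: MMatrix, covariates: pd.DataFrame) -> MMatrix:
    """Replace each probe's M-values by OLS residuals on the covariates.

    An intercept is always included, so residuals are centered and
    uncorrelated with every covariate. Used to adjust comparisons (e.g.
    CTNNB1 wild-type vs mutated) for numeric confounders such as age at
    diagnosis or alpha-fetoprotein level.
    """
    missing = [s for s in m.samples if s not in covariates.index]
    if missing:
        raise ValidationError(f"covariates missing for samples: {missing[:5]}")
    X = covariates.loc[list(m.samples)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("covariates contain missing values")
    X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("covariate matrix is rank-deficient (collinear columns?)")
    # residual-maker matrix: R = I - X (X'X)^-1 X'
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    resid = m.values.to_numpy() @ (np.eye(len(X)) - hat).T
    return MMatrix(
        values=pd.DataFrame(resid, index=m.probe_ids, columns=m.samples),
        metadata=m.metadata.copy(),
        epsilon=m.epsilon,
    )


def pca_covariate_screen(m: MMatrix, covariates: pd.DataFrame, n_components: int = 5) -> pd.DataFrame:
    """Correlate top principal components of the M-matrix with covariates.

    A quick screen for unwanted covariate-driven structure: returns a
    (component x covariate) table of Pearson correlations. Large absolute
    values suggest residualization is warranted.
    """
    X = m.values.to_numpy().T  # samples x probes
    X = X - X.mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    cov = covariates.loc[list(m.samples)].to_numpy(dtype=float)
    out = np.zeros((n_components, cov.shape[1]))
    for i in range(n_components):
        for j in range(cov.shape[1]):
            out[i, j] = np.corrcoef(scores[:, i], cov[:, j])[0, 1]
    return pd.DataFrame(out, index=[f"PC{i+1}" for i in range(n_components)], columns=covariates.columns)
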