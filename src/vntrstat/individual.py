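"""Individual-level VNTR association (VNTR.g) and marginal tag-SNP GWAS.

VNTR.g regresses the phenotype on the predicted VNTR dosage jointly with
covariates.  The companion :func:`marginal_gwas` produces per-SNP summary
statistics from the same cohort — each SNP and the phenotype are first
residualized on the covariates, then normalized (denominator-n) so the
marginal effect equals the SNP-phenotype correlation — which is exactly
the input the summary-statistics test expects.  Running both on one cohort
is the concordance experiment validating VNTR.s against VNTR.g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sp_stats

from .errors import DegeneratePredictorError
from .panel import TagPanel
from .prediction import PredictionModel, predict_vntr_dosage
from .summary_assoc import SummaryStats, VNTRAssocResult, zscore_to_pvalue

__all__ = ["PhenotypeData", "run_vntr_g", "marginal_gwas", "inverse_normal_transform"]

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeData:
    """Phenotype vector with optional covariates (age, sex, ancestry PCs...)."""

    sample_ids: list
    y: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.sample_ids)
        if self.y.shape != (n,):
            raise ValueError("y length must match sample_ids")
        if np.isnan(self.y).any():
            raise ValueError("missing phenotype values; apply QC first")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.size == 0:
                self.covariates = None
            else:
                if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
                    raise ValueError("covariates must be (n_samples, k)")
                if np.isnan(self.covariates).any():
                    raise ValueError("missing covariate values")
                k = self.covariates.shape[1]
                if np.linalg.matrix_rank(
                    np.column_stack([np.ones(n), self.covariates])
                ) < k + 1:
                    raise ValueError("covariate matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset 3/8), optional pre-step."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    ranks = sp_stats.rankdata(y, method="average")
    return sp_stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of v on [1, covariates] (always removes the mean)."""
    n = len(v)
    design = (
        np.ones((n, 1))
        if covariates is None
        else np.column_stack([np.ones(n), covariates])
    )
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def run_vntr_g(
    model: PredictionModel,
    panel: TagPanel,
    phenotype: PhenotypeData,
    inverse_normal: bool = False,
) -> VNTRAssocResult:
    """Regress the phenotype on predicted VNTR dosage plus covariates.

    The predicted dosage enters jointly with the covariates in one OLS fit;
    the reported effect, SE, t-based z, and two-sided p belong to the
    predicted-dosage coefficient.  The phenotype is residualized on nothing
    here — covariate adjustment is part of the joint regression.
    """
    if panel.sample_ids != phenotype.sample_ids:
        panel = panel.reorder_samples(phenotype.sample_ids)
    y = phenotype.y
    if inverse_normal:
        y = inverse_normal_transform(y)
    g_hat = predict_vntr_dosage(model, panel)
    if g_hat.std() == 0:
        raise DegeneratePredictorError("predicted VNTR dosage is constant")
    n = len(y)
    design = [np.ones(n), g_hat]
    if phenotype.covariates is not None:
        design.append(phenotype.covariates)
    x = np.column_stack(design)
    fit = sm.OLS(y, x).fit()
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    # same-sample quadratic form: var(G_hat) = w' V_sample w
    k_wv = float(g_hat.var())
    return VNTRAssocResult(
        alpha_hat=coef,
        var_alpha=se**2,
        z_alpha=t,
        p_value=p,
        k_wv=k_wv,
        n_used=float(n),
        snps_used=list(model.snp_ids),
        snps_dropped=list(model.dropped_snps),
        mode_flags={
            "model_mode": model.mode,
            "covariates": phenotype.n_covariates,
            "inverse_normal": inverse_normal,
            "p_basis": "t",
        },
        method="VNTR.g",
        sigma2_y=float(y.var()),
    )


def marginal_gwas(
    panel: TagPanel,
    phenotype: PhenotypeData,
    inverse_normal: bool = False,
) -> SummaryStats:
    """Per-SNP marginal association scan producing summary statistics.

    For each tag SNP, both the phenotype and the SNP dosage are
    residualized on the covariates (plus intercept), normalized to unit
    denominator-n variance, and the simple regression ``Y = X_j b_j + e_j``
    is evaluated in closed form: ``b_j = (1/n) X_j'Y = corr(x_j, Y)``.  The
    reported ``z`` is the OLS t-statistic with ``n - 2 - k`` residual
    degrees of freedom (k covariates); ``p`` is two-sided normal, the GWAS
    convention.  Monomorphic SNPs are dropped with a warning.
    """
    if panel.sample_ids != phenotype.sample_ids:
        panel = panel.reorder_samples(phenotype.sample_ids)
    n = phenotype.n_samples
    k = phenotype.n_covariates
    y = phenotype.y
    if inverse_normal:
        y = inverse_normal_transform(y)
    yr = _residualize(y, phenotype.covariates)
    ysd = yr.std()
    if ysd == 0:
        raise ValueError("phenotype constant after residualization")
    yn = yr / ysd

    keep, betas, ses, zs = [], [], [], []
    df = n - 2 - k
    for j, snp in enumerate(panel.snp_ids):
        xj = panel.genotypes[:, j]
        if xj.std() == 0:
            logger.warning("dropping monomorphic SNP %s from the GWAS", snp)
            continue
        xr = _residualize(xj, phenotype.covariates)
        if xr.std() == 0:
            logger.warning("dropping SNP %s (constant after residualization)", snp)
            continue
        xn = xr / xr.std()
        b = float(xn @ yn) / n  # correlation on the normalized scale
        b = float(np.clip(b, -1.0, 1.0))
        t = b * np.sqrt(df / max(1.0 - b * b, 1e-300))
        se = b / t if t != 0 else np.sqrt(1.0 / df)
        keep.append(j)
        betas.append(b)
        ses.append(abs(se))
        zs.append(t)

    if not keep:
        raise ValueError("no polymorphic SNPs left for the GWAS")
    zs = np.asarray(zs)
    return SummaryStats(
        snp_ids=[panel.snp_ids[j] for j in keep],
        effect_alleles=[panel.effect_alleles[j] for j in keep],
        other_alleles=(
            [panel.other_alleles[j] for j in keep]
            if panel.other_alleles is not None
            else ["N"] * len(keep)
        ),
        n=np.full(len(keep), float(n)),
        beta=np.asarray(betas),
        se=np.asarray(ses),
        z=zs,
        p=np.asarray([zscore_to_pvalue(z) for z in zs]),
    )
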