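"""The summary-statistics VNTR association test (VNTR.s).

Given (i) prediction weights ``w`` mapping normalized tag-SNP dosages to
VNTR dosage, (ii) per-SNP marginal GWAS effects ``b`` (or Z-scores ``Z_b``)
for a phenotype ``Y``, and (iii) a tag-SNP LD matrix ``V``, the effect of
the (unobserved) VNTR on ``Y`` is estimated and tested without any
individual-level data::

    alpha_hat = w'b / (w'Vw)
    var(alpha_hat) = sigma_y^2 / (n * K_wv),   K_wv = w'Vw
    Z_alpha = w'Z_b / sqrt(w'Vw)

``Z_alpha`` is asymptotically standard normal under ``alpha = 0``; the
two-sided p-value is the survival function of a chi-square with one degree
of freedom at ``Z_alpha**2``.  The construction mirrors TWAS-style tests
that combine marginal Z-scores through imputation weights, and on a single
sample (same-sample ``V``, ``Z_b = sqrt(n) * corr(x_j, Y)``) it is
algebraically identical to regressing ``Y`` on the predicted dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    AlleleMismatchError,
    DegenerateWeightsError,
    NoUsableSNPsError,
    VntrStatError,
)
from .ld import LDMatrix, regularize_ld
from .panel import classify_allele_pair, complement_allele, is_palindromic
from .prediction import PredictionModel, subset_model

__all__ = [
    "SummaryStats",
    "VNTRAssocResult",
    "harmonize",
    "estimate_alpha",
    "alpha_variance",
    "vntr_s_zscore",
    "zscore_to_pvalue",
    "test_summary",
]

logger = logging.getLogger(__name__)

#: K_wv below this is treated as carrying no LD-adjusted signal.
K_WV_TOL = 1e-10


@dataclass
class SummaryStats:
    """Per-SNP marginal GWAS summary statistics.

    For every SNP at least one of ``(beta, se)`` or ``z`` must be present;
    a missing ``z`` is derived as ``beta / se``.  ``n`` may be a scalar or
    per-SNP vector.  When both effect-size and Z representations are given
    they must agree to 1e-6 relative — silent disagreement usually means a
    corrupt file.
    """

    snp_ids: list
    effect_alleles: list
    other_alleles: list
    n: np.ndarray
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    z: np.ndarray | None = None
    p: np.ndarray | None = None

    def __post_init__(self):
        m = len(self.snp_ids)
        if len(self.effect_alleles) != m or len(self.other_alleles) != m:
            raise ValueError("allele lists must match snp_ids length")
        self.n = np.broadcast_to(np.asarray(self.n, dtype=float), (m,)).copy()
        for name in ("beta", "se", "z", "p"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (m,):
                    raise ValueError(f"{name} length must equal snp_ids length")
                setattr(self, name, v)
        if self.beta is None and self.z is None:
            raise ValueError("need beta+se or z")
        if self.beta is not None:
            if self.se is None:
                raise ValueError("beta requires se")
            if (self.se <= 0).any():
                raise ValueError("se must be positive")
            z_from_beta = self.beta / self.se
            if self.z is None:
                self.z = z_from_beta
            else:
                denom = np.maximum(np.abs(self.z), 1e-12)
                rel = np.abs(self.z - z_from_beta) / denom
                if (rel > 1e-6).any():
                    bad = [self.snp_ids[j] for j in np.flatnonzero(rel > 1e-6)]
                    raise VntrStatError(
                        "z disagrees with beta/se beyond 1e-6 relative for: "
                        + ", ".join(bad)
                    )
        if not np.isfinite(self.z).all():
            raise ValueError("z must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids) -> "SummaryStats":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        pick = lambda v: None if v is None else v[idx]
        return SummaryStats(
            snp_ids=[self.snp_ids[j] for j in idx],
            effect_alleles=[self.effect_alleles[j] for j in idx],
            other_alleles=[self.other_alleles[j] for j in idx],
            n=self.n[idx],
            beta=pick(self.beta),
            se=pick(self.se),
            z=pick(self.z),
            p=pick(self.p),
        )


@dataclass
class VNTRAssocResult:
    """Outcome of a VNTR-phenotype association test."""

    alpha_hat: float
    var_alpha: float
    z_alpha: float
    p_value: float
    k_wv: float
    n_used: float
    snps_used: list
    snps_dropped: list = field(default_factory=list)
    mode_flags: dict = field(default_factory=dict)
    method: str = "VNTR.s"
    sigma2_y: float = 1.0

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.var_alpha))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha_hat": self.alpha_hat,
            "se_alpha": self.se_alpha,
            "var_alpha": self.var_alpha,
            "z_alpha": self.z_alpha,
            "p_value": self.p_value,
            "k_wv": self.k_wv,
            "n_used": self.n_used,
            "sigma2_y": self.sigma2_y,
            "snps_used": list(self.snps_used),
            "snps_dropped": list(self.snps_dropped),
            "mode_flags": dict(self.mode_flags),
        }


def harmonize(
    stats_in: SummaryStats,
    model: PredictionModel,
    ld: LDMatrix,
    palindromic: str = "keep",
):
    """Align summary statistics, model, and LD matrix on a common SNP set.

    All three inputs are restricted to the intersection of their SNP ids in
    the model's order.  Where a summary record codes the model's *other*
    allele, the signs of its ``beta``/``z`` are flipped and the matching LD
    row/column is sign-flipped.  Strand-ambiguous (A/T, C/G) SNPs are kept
    with id-based matching and a logged warning by default
    (``palindromic='keep'``) or removed (``'drop'``).

    Returns the aligned ``(stats, model, ld)`` triple; SNPs dropped from
    the model are recorded on the returned model.
    """
    if palindromic not in ("keep", "drop"):
        raise ValueError("palindromic must be 'keep' or 'drop'")
    common = [
        s for s in model.snp_ids if s in set(stats_in.snp_ids) and s in set(ld.snp_ids)
    ]
    if palindromic == "drop":
        kept = []
        for s in common:
            j = model.snp_ids.index(s)
            oa = model.other_alleles[j] if model.other_alleles else None
            if oa is not None and is_palindromic(model.effect_alleles[j], oa):
                logger.warning("dropping strand-ambiguous SNP %s", s)
            else:
                kept.append(s)
        common = kept
    if not common:
        raise NoUsableSNPsError("no SNPs shared by summary stats, model, and LD")

    m = subset_model(model, common) if common != model.snp_ids else model
    s = stats_in.subset(common)
    v = ld.subset(common)

    def _orient(coded_eff, coded_oth, snp, what):
        """Sign of a coded quantity relative to the model's allele coding."""
        mo = m.other_alleles[snp_index[snp]] if m.other_alleles else None
        me = m.effect_alleles[snp_index[snp]]
        if mo is None or coded_oth is None:
            if coded_eff.upper() == me.upper() or (
                complement_allele(coded_eff) == me.upper()
            ):
                return 1.0
            raise AlleleMismatchError(
                f"cannot orient {what} of {snp}: coded allele {coded_eff} "
                f"does not match model allele {me} and pair info is missing"
            )
        rel = classify_allele_pair(coded_eff, coded_oth, me, mo)
        if rel is None:
            raise AlleleMismatchError(
                f"alleles {coded_eff}/{coded_oth} of {snp} irreconcilable "
                f"with model {me}/{mo} in {what}"
            )
        if is_palindromic(me, mo):
            logger.warning(
                "strand-ambiguous SNP %s retained with id-based matching", snp
            )
        return -1.0 if rel == "flip" else 1.0

    snp_index = {snp: j for j, snp in enumerate(common)}
    sign_stats = np.array(
        [
            _orient(s.effect_alleles[j], s.other_alleles[j], snp, "summary stats")
            for j, snp in enumerate(common)
        ]
    )
    if (sign_stats < 0).any():
        for snp in (c for j, c in enumerate(common) if sign_stats[j] < 0):
            logger.info("flipping effect sign of %s to the model allele", snp)
        flip = lambda arr: None if arr is None else arr * sign_stats
        s = SummaryStats(
            snp_ids=s.snp_ids,
            effect_alleles=list(m.effect_alleles),
            other_alleles=(
                list(m.other_alleles) if m.other_alleles else list(s.other_alleles)
            ),
            n=s.n,
            beta=flip(s.beta),
            se=s.se,
            z=flip(s.z),
            p=s.p,
        )
    if v.effect_alleles is not None:
        sign_ld = np.array(
            [
                _orient(
                    v.effect_alleles[j],
                    None if v.other_alleles is None else v.other_alleles[j],
                    snp,
                    "LD panel",
                )
                for j, snp in enumerate(common)
            ]
        )
        if (sign_ld < 0).any():
            v = LDMatrix(
                snp_ids=v.snp_ids,
                values=v.values * np.outer(sign_ld, sign_ld),
                n_panel=v.n_panel,
                source=v.source,
                epsilon=v.epsilon,
                effect_alleles=list(m.effect_alleles),
                other_alleles=(
                    list(m.other_alleles) if m.other_alleles else None
                ),
            )
    return s, m, v


def estimate_alpha(weights, betas, ld_values) -> float:
    """Point estimate ``w'b / (w'Vw)`` of the VNTR effect."""
    w = np.asarray(weights, dtype=float)
    b = np.asarray(betas, dtype=float)
    v = np.asarray(ld_values, dtype=float)
    k = float(w @ v @ w)
    if k <= K_WV_TOL:
        raise DegenerateWeightsError(
            f"K_wv = {k:.3g} <= {K_WV_TOL}; weights carry no LD-adjusted signal"
        )
    return float(w @ b) / k


def alpha_variance(weights, ld_values, n, sigma2_y: float = 1.0):
    """Variance ``sigma_y^2 / (n K_wv)`` of the estimated VNTR effect.

    Returns ``(var, k_wv)``.
    """
    w = np.asarray(weights, dtype=float)
    v = np.asarray(ld_values, dtype=float)
    k = float(w @ v @ w)
    if k <= K_WV_TOL:
        raise DegenerateWeightsError(f"K_wv = {k:.3g} <= {K_WV_TOL}")
    n = float(n)
    if n <= 0:
        raise ValueError("n must be positive")
    if sigma2_y <= 0:
        raise ValueError("sigma2_y must be positive")
    return sigma2_y / (n * k), k


def vntr_s_zscore(weights, zscores, ld_values) -> float:
    """Combined Z-statistic ``w'Z_b / sqrt(w'Vw)``.

    Invariant to positive rescaling of the weights; asymptotically standard
    normal when the VNTR has no effect.
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(zscores, dtype=float)
    v = np.asarray(ld_values, dtype=float)
    k = float(w @ v @ w)
    if k <= K_WV_TOL:
        raise DegenerateWeightsError(f"K_wv = {k:.3g} <= {K_WV_TOL}")
    return float(w @ z) / float(np.sqrt(k))


def zscore_to_pvalue(z: float) -> float:
    """Two-sided p-value: ``P(U > z^2)`` with ``U ~ chi2(1)``."""
    z = float(z)
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(stats.chi2.sf(z * z, df=1))


def test_summary(
    model: PredictionModel,
    stats_in: SummaryStats,
    ld: LDMatrix,
    sigma2_y: float = 1.0,
    epsilon: float = 0.001,
    palindromic: str = "keep",
) -> VNTRAssocResult:
    """Run the full summary-statistics VNTR association test.

    Harmonizes the inputs, shrinks the LD matrix by ``epsilon`` (set 0 to
    disable), and evaluates effect, variance, Z, and p-value.  ``sigma2_y``
    defaults to 1, the convention for phenotypes normalized before GWAS;
    override only for unnormalized traits (rescales ``var(alpha_hat)``
    only).
    """
    s, m, v = harmonize(stats_in, model, ld, palindromic=palindromic)
    if epsilon > 0:
        v = regularize_ld(v, epsilon)
    n_vec = np.asarray(s.n, dtype=float)
    n_used = float(np.median(n_vec))
    if n_vec.max() > n_vec.min():
        logger.warning(
            "heterogeneous per-SNP n in [%g, %g]; using median %g",
            n_vec.min(), n_vec.max(), n_used,
        )
    w = m.weights
    if s.beta is not None:
        alpha = estimate_alpha(w, s.beta, v.values)
    else:
        # beta unavailable: alpha on the z scale, beta_j ~ z_j / sqrt(n)
        alpha = estimate_alpha(w, s.z / np.sqrt(n_vec), v.values)
    var_a, k = alpha_variance(w, v.values, n_used, sigma2_y)
    z_a = vntr_s_zscore(w, s.z, v.values)
    return VNTRAssocResult(
        alpha_hat=alpha,
        var_alpha=var_a,
        z_alpha=z_a,
        p_value=zscore_to_pvalue(z_a),
        k_wv=k,
        n_used=n_used,
        snps_used=list(m.snp_ids),
        snps_dropped=list(m.dropped_snps),
        mode_flags={
            "model_mode": m.mode,
            "epsilon": v.epsilon,
            "palindromic": palindromic,
            "sigma2_y": sigma2_y,
        },
        method="VNTR.s",
        sigma2_y=sigma2_y,
    )
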