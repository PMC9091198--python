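"""Linear prediction of VNTR allele dosage from tag-SNP genotypes.

The VNTR dosage ``g`` (count of long alleles) is modelled as a linear
function of the normalized tag-SNP dosages::

    g = delta + w_1 x_1 + ... + w_m x_m + eps

Weights are the least-squares solution ``(X'X)^-1 X'G`` on the normalized
design; the intercept is the training mean of ``g`` (predictors are
centered).  The fitted model is portable: applied to a new cohort it yields
a continuous predicted dosage ``G_hat`` on the interpretable 0-2 scale, and
its weight vector is the ``w`` entering the summary-statistics test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CollinearityError,
    InsufficientSampleError,
    MonomorphicSNPError,
    NoUsableSNPsError,
)
from .panel import TagPanel, normalize_genotypes

__all__ = [
    "PredictionModel",
    "fit_prediction_weights",
    "predict_vntr_dosage",
    "subset_model",
    "vntr_tag_ld",
]

logger = logging.getLogger(__name__)

# Condition-number threshold beyond which the normalized design is treated
# as rank deficient.
_COND_MAX = 1e10


@dataclass
class PredictionModel:
    """Fitted tag-SNP -> VNTR dosage linear predictor.

    ``weights`` are on the normalized-dosage scale (one unit = one
    denominator-n standard deviation of the tag-SNP dosage); ``intercept``
    is the training mean VNTR dosage.  ``vntr_tag_ld`` stores the Pearson
    correlation of each tag SNP with the VNTR dosage in the training panel.
    """

    snp_ids: list
    effect_alleles: list
    weights: np.ndarray
    intercept: float
    n_train: int
    r2_train: float
    vntr_tag_ld: np.ndarray
    other_alleles: list | None = None
    dropped_snps: list = field(default_factory=list)
    mode: str = "full"  # full | subset | refit
    ridge: float = 0.0
    genome_build: str = "GRCh38"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.vntr_tag_ld = np.asarray(self.vntr_tag_ld, dtype=float)
        m = len(self.snp_ids)
        if self.weights.shape != (m,):
            raise ValueError("weights length must equal snp_ids length")
        if self.vntr_tag_ld.shape != (m,):
            raise ValueError("vntr_tag_ld length must equal snp_ids length")
        if not -1e-9 <= self.r2_train <= 1 + 1e-9:
            raise ValueError("r2_train must lie in [0, 1]")
        if np.abs(self.vntr_tag_ld).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("|vntr_tag_ld| must be <= 1")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_dict(self) -> dict:
        return {
            "snp_ids": list(self.snp_ids),
            "effect_alleles": list(self.effect_alleles),
            "other_alleles": None if self.other_alleles is None else list(self.other_alleles),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "n_train": int(self.n_train),
            "r2_train": float(self.r2_train),
            "vntr_tag_ld": self.vntr_tag_ld.tolist(),
            "dropped_snps": list(self.dropped_snps),
            "mode": self.mode,
            "ridge": float(self.ridge),
            "genome_build": self.genome_build,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionModel":
        return cls(
            snp_ids=d["snp_ids"],
            effect_alleles=d["effect_alleles"],
            other_alleles=d.get("other_alleles"),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=d["intercept"],
            n_train=d["n_train"],
            r2_train=d["r2_train"],
            vntr_tag_ld=np.asarray(d["vntr_tag_ld"], dtype=float),
            dropped_snps=d.get("dropped_snps", []),
            mode=d.get("mode", "full"),
            ridge=d.get("ridge", 0.0),
            genome_build=d.get("genome_build", "GRCh38"),
        )


def vntr_tag_ld(panel: TagPanel) -> np.ndarray:
    """Pearson correlation of each tag-SNP dosage with the VNTR dosage."""
    if panel.vntr_dosage is None:
        raise ValueError("panel has no VNTR dosages")
    x = panel.normalized()
    g = panel.vntr_dosage
    gsd = g.std()
    if gsd == 0:
        raise MonomorphicSNPError(["VNTR"])
    gz = (g - g.mean()) / gsd
    return x.T @ gz / panel.n_samples


def fit_prediction_weights(panel: TagPanel, ridge: float = 0.0) -> PredictionModel:
    """Least-squares fit of VNTR dosage on normalized tag-SNP dosages.

    Parameters
    ----------
    panel
        Training panel carrying ``vntr_dosage``.
    ridge
        Optional ridge penalty ``lambda`` added as ``n * lambda`` to the
        diagonal of the normal equations; default 0 (plain OLS).  Useful
        for small panels with near-collinear tags.

    Raises
    ------
    InsufficientSampleError
        If the panel has no more samples than SNPs.
    CollinearityError
        If the normalized design is rank deficient (and ``ridge == 0``),
        listing the dependent SNPs.
    """
    if panel.vntr_dosage is None:
        raise ValueError("training panel must carry vntr_dosage")
    n, m = panel.genotypes.shape
    if n <= m:
        raise InsufficientSampleError(
            f"need more samples ({n}) than SNPs ({m}) to fit the prediction model"
        )
    x = panel.normalized()
    g = panel.vntr_dosage.astype(float)

    xtx = x.T @ x
    if ridge == 0.0:
        if np.linalg.cond(xtx) > _COND_MAX:
            # identify columns involved in the dependency via QR pivoting
            q, r, piv = _qr_pivot(x)
            rank = int((np.abs(np.diag(r)) > np.abs(r[0, 0]) * 1e-12).sum())
            dep = [panel.snp_ids[j] for j in sorted(piv[rank:])]
            raise CollinearityError(
                "normalized design is rank deficient; dependent SNPs: "
                + ", ".join(dep)
                + " (consider ridge > 0)"
            )
        weights = np.linalg.solve(xtx, x.T @ g)
    else:
        weights = np.linalg.solve(xtx + n * ridge * np.eye(m), x.T @ g)

    intercept = float(g.mean())
    resid = g - intercept - x @ weights
    tss = float(((g - g.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    return PredictionModel(
        snp_ids=list(panel.snp_ids),
        effect_alleles=list(panel.effect_alleles),
        other_alleles=None if panel.other_alleles is None else list(panel.other_alleles),
        weights=weights,
        intercept=intercept,
        n_train=n,
        r2_train=max(0.0, min(1.0, r2)),
        vntr_tag_ld=vntr_tag_ld(panel),
        ridge=ridge,
    )


def _qr_pivot(x):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def predict_vntr_dosage(model: PredictionModel, panel: TagPanel) -> np.ndarray:
    """Predicted (continuous) VNTR dosage for each sample of ``panel``.

    The panel's columns must cover the model SNPs; genotypes are normalized
    within the target cohort before applying the weights, and the intercept
    puts predictions back on the 0-2 dosage scale.
    """
    missing = [s for s in model.snp_ids if s not in panel.snp_ids]
    if missing:
        raise NoUsableSNPsError(
            "panel lacks model SNPs: "
            + ", ".join(missing)
            + "; restrict the model first with subset_model()"
        )
    sub = panel.subset_snps(model.snp_ids)
    flip = _flip_mask(model, sub)
    geno = sub.genotypes.copy()
    geno[:, flip] = 2.0 - geno[:, flip]
    x = normalize_genotypes(geno, sub.snp_ids)
    return x @ model.weights + model.intercept


def _flip_mask(model: PredictionModel, panel: TagPanel) -> np.ndarray:
    """Boolean mask of panel columns whose coded allele is the model's other allele."""
    from .errors import AlleleMismatchError
    from .panel import complement_allele

    flip = np.zeros(panel.n_snps, dtype=bool)
    for j, snp in enumerate(panel.snp_ids):
        pa = panel.effect_alleles[j].upper()
        ma = model.effect_alleles[j].upper()
        mo = (
            model.other_alleles[j].upper()
            if model.other_alleles is not None
            else None
        )
        if pa == ma or complement_allele(pa) == ma:
            continue
        if mo is not None and (pa == mo or complement_allele(pa) == mo):
            flip[j] = True
            logger.warning("flipping dosage of %s to the model effect allele", snp)
            continue
        raise AlleleMismatchError(
            f"allele {pa} of {snp} matches neither model allele "
            f"({ma}/{mo if mo else '?'})"
        )
    return flip


def subset_model(
    model: PredictionModel,
    available_snp_ids,
    refit_panel: TagPanel | None = None,
) -> PredictionModel:
    """Restrict a model to the SNPs available in a target dataset.

    Default behavior keeps the original weights of retained SNPs
    (``mode='subset'``) because the reference procedure treats the training
    weights as fixed downstream.  Passing ``refit_panel`` re-estimates the
    weights on that panel restricted to the available SNPs
    (``mode='refit'``).  Dropped SNP ids are recorded on the result.
    """
    keep = [s for s in model.snp_ids if s in set(available_snp_ids)]
    if not keep:
        raise NoUsableSNPsError("no model SNPs among available_snp_ids")
    dropped = [s for s in model.snp_ids if s not in set(available_snp_ids)]
    if refit_panel is not None:
        refit = fit_prediction_weights(refit_panel.subset_snps(keep), ridge=model.ridge)
        refit.dropped_snps = list(model.dropped_snps) + dropped
        refit.mode = "refit" if dropped else model.mode
        return refit
    idx = [model.snp_ids.index(s) for s in keep]
    return PredictionModel(
        snp_ids=keep,
        effect_alleles=[model.effect_alleles[j] for j in idx],
        other_alleles=(
            None
            if model.other_alleles is None
            else [model.other_alleles[j] for j in idx]
        ),
        weights=model.weights[idx],
        intercept=model.intercept,
        n_train=model.n_train,
        r2_train=model.r2_train,
        vntr_tag_ld=model.vntr_tag_ld[idx],
        dropped_snps=list(model.dropped_snps) + dropped,
        mode="subset" if dropped else model.mode,
        ridge=model.ridge,
        genome_build=model.genome_build,
    )
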