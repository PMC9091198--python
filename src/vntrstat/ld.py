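"""Tag-SNP LD matrices: estimation, panel merging, shrinkage.

The summary-statistics test needs the correlation matrix ``V`` of the tag
SNPs, estimated from a reference genotype panel.  Following the reference
procedure, multiple panels (e.g. a small training cohort plus a public
European panel) are pooled at the sample level and ``V`` is computed on the
merged panel, not averaged across panels.

``V`` enters the test only through the quadratic form ``w'Vw``; a small
convex shrinkage toward the identity guards that form against sampling
noise in modest reference panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import IncompatiblePanelsError
from .panel import TagPanel, classify_allele_pair, complement_allele

__all__ = ["LDMatrix", "compute_ld", "merge_panels", "regularize_ld"]

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """SNP x SNP Pearson-correlation matrix with provenance.

    ``effect_alleles``/``other_alleles`` record the dosage coding of the
    panel the matrix was estimated on, enabling sign harmonization against
    a prediction model coded differently; they are optional, in which case
    the matrix is assumed to share the model's coding.
    """

    snp_ids: list
    values: np.ndarray
    n_panel: int
    source: str = ""
    epsilon: float = 0.0  # shrinkage already applied
    effect_alleles: list | None = None
    other_alleles: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.snp_ids)
        if self.values.shape != (m, m):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("LD matrix must have unit diagonal")
        if np.abs(self.values).max() > 1 + 1e-9:
            raise ValueError("LD entries must lie in [-1, 1]")

    def subset(self, snp_ids) -> "LDMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        pick = lambda xs: None if xs is None else [xs[i] for i in idx]
        return replace(
            self,
            snp_ids=list(snp_ids),
            values=self.values[np.ix_(idx, idx)],
            effect_alleles=pick(self.effect_alleles),
            other_alleles=pick(self.other_alleles),
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())


def compute_ld(panel: TagPanel, source: str | None = None) -> LDMatrix:
    """Pairwise Pearson correlation of dosage columns.

    Equivalently ``(1/n) X'X`` on the denominator-n normalized genotypes,
    so ``X'X = n V`` holds exactly.
    """
    x = panel.normalized()
    n = panel.n_samples
    v = x.T @ x / n
    np.fill_diagonal(v, 1.0)
    v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
    return LDMatrix(
        snp_ids=list(panel.snp_ids),
        values=v,
        n_panel=n,
        source=source if source is not None else (panel.source or "panel"),
        effect_alleles=list(panel.effect_alleles),
        other_alleles=None if panel.other_alleles is None else list(panel.other_alleles),
    )


def merge_panels(panels: list[TagPanel]) -> TagPanel:
    """Row-concatenate panels sharing the same SNPs after harmonization.

    Panels must cover identical SNP id sets and have disjoint sample ids.
    Where a later panel codes a SNP by the opposite allele, its dosages are
    flipped (``d -> 2 - d``) to the first panel's convention; an allele pair
    that matches neither directly nor by strand complement is an error.
    """
    if not panels:
        raise ValueError("no panels to merge")
    ref = panels[0]
    pieces = [ref]
    for p in panels[1:]:
        if set(p.snp_ids) != set(ref.snp_ids):
            raise IncompatiblePanelsError("panels cover different SNP sets")
        p = p.subset_snps(ref.snp_ids)
        geno = p.genotypes.copy()
        eff = list(p.effect_alleles)
        for j, snp in enumerate(ref.snp_ids):
            pa = p.effect_alleles[j]
            ra = ref.effect_alleles[j]
            po = p.other_alleles[j] if p.other_alleles is not None else None
            ro = ref.other_alleles[j] if ref.other_alleles is not None else None
            if po is not None and ro is not None:
                rel = classify_allele_pair(pa, po, ra, ro)
            elif pa.upper() == ra.upper() or complement_allele(pa) == ra.upper():
                rel = "same"
            else:
                rel = None
            if rel is None:
                raise IncompatiblePanelsError(
                    f"effect allele {pa} of {snp} irreconcilable with {ra}"
                )
            if rel == "flip":
                logger.info("flipping %s to the first panel's effect allele", snp)
                geno[:, j] = 2.0 - geno[:, j]
            eff[j] = ref.effect_alleles[j]
        pieces.append(
            TagPanel(
                sample_ids=p.sample_ids,
                snp_ids=list(ref.snp_ids),
                effect_alleles=eff,
                other_alleles=None if ref.other_alleles is None else list(ref.other_alleles),
                genotypes=geno,
                vntr_dosage=p.vntr_dosage,
                source=p.source,
            )
        )
    all_ids = [s for p in pieces for s in p.sample_ids]
    if len(set(all_ids)) != len(all_ids):
        raise IncompatiblePanelsError("duplicate sample ids across panels")
    have_vntr = all(p.vntr_dosage is not None for p in pieces)
    return TagPanel(
        sample_ids=all_ids,
        snp_ids=list(ref.snp_ids),
        effect_alleles=list(ref.effect_alleles),
        other_alleles=None if ref.other_alleles is None else list(ref.other_alleles),
        genotypes=np.vstack([p.genotypes for p in pieces]),
        vntr_dosage=(
            np.concatenate([p.vntr_dosage for p in pieces]) if have_vntr else None
        ),
        source="merged panel (" + " + ".join(p.source or "?" for p in pieces) + ")",
    )


def regularize_ld(ld: LDMatrix, epsilon: float = 0.001) -> LDMatrix:
    """Convex shrinkage ``(1 - eps) V + eps I`` toward the identity.

    The shrunk matrix keeps a unit diagonal by construction.  If the result
    is still indefinite (possible only for an inconsistent input), ``eps``
    is escalated tenfold with a log message until the smallest eigenvalue
    is nonnegative (within 1e-10).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    eps = float(epsilon)
    v = ld.values.copy()
    while True:
        shrunk = (1.0 - eps) * v + eps * np.eye(len(ld.snp_ids))
        d = np.sqrt(np.diag(shrunk))
        shrunk = shrunk / np.outer(d, d)
        np.fill_diagonal(shrunk, 1.0)
        if np.linalg.eigvalsh(shrunk).min() >= -1e-10 or eps >= 1.0:
            break
        eps = min(1.0, 10.0 * eps) if eps > 0 else 1e-4
        logger.warning("LD matrix still indefinite; escalating shrinkage to %g", eps)
    return replace(ld, values=shrunk, epsilon=eps)
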