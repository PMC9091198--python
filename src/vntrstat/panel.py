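"""Genotype panels and dosage normalization.

A :class:`TagPanel` holds per-sample allele dosages for the tag SNPs of a
VNTR locus, optionally together with the VNTR dosage itself (the count of
long alleles, 0/1/2).  Panels are the unit of training (fitting prediction
weights), of LD estimation, and of simulation output.

Normalization follows the denominator-``n`` convention: each column is
centered and scaled by the population-style standard deviation
``sqrt(mean((x - mean(x))**2))`` so that for the normalized design matrix
``X`` the identity ``X'X = n V`` holds exactly, with ``V`` the sample
correlation matrix.  This makes the summary-statistics test algebraically
identical to the individual-level one on the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import MonomorphicSNPError

__all__ = ["TagPanel", "normalize_genotypes"]


def normalize_genotypes(genotypes: np.ndarray, snp_ids=None) -> np.ndarray:
    """Center each column and scale to unit denominator-n variance.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` dosage matrix without missing entries.
    snp_ids
        Optional identifiers used in error messages.

    Returns
    -------
    numpy.ndarray
        Matrix whose columns have mean 0 and sum of squares exactly
        ``n_samples``.

    Raises
    ------
    MonomorphicSNPError
        If any column has zero variance.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D samples x SNPs matrix")
    sd = g.std(axis=0)  # denominator-n
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        ids = (
            [str(snp_ids[j]) for j in bad]
            if snp_ids is not None
            else [f"column {j}" for j in bad]
        )
        raise MonomorphicSNPError(ids)
    return (g - g.mean(axis=0)) / sd


# IUPAC complement for strand flips during allele harmonization
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in allele.upper()[::-1])


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous pairs (A/T or C/G)."""
    return complement_allele(a1) == a2.upper()


def classify_allele_pair(a1: str, a2: str, b1: str, b2: str) -> str | None:
    """Relate coded allele pair (a1, a2) to reference pair (b1, b2).

    Returns ``"same"`` when the coding agrees (directly or on the opposite
    strand), ``"flip"`` when the coded allele is the reference's other
    allele, and ``None`` when the pairs are irreconcilable.
    """
    a1, a2, b1, b2 = (x.upper() for x in (a1, a2, b1, b2))
    if (a1, a2) == (b1, b2):
        return "same"
    if (a1, a2) == (b2, b1):
        return "flip"
    ca1, ca2 = complement_allele(a1), complement_allele(a2)
    if (ca1, ca2) == (b1, b2):
        return "same"
    if (ca1, ca2) == (b2, b1):
        return "flip"
    return None


@dataclass
class TagPanel:
    """Per-sample tag-SNP dosages, optionally with the VNTR dosage.

    Attributes
    ----------
    sample_ids, snp_ids : list of str
    effect_alleles : list of str
        The allele whose count is the coded dosage, one per SNP.
    other_alleles : list of str or None
        The non-effect allele; needed for harmonization against summary
        statistics, optional otherwise.
    genotypes : numpy.ndarray
        ``(n_samples, n_snps)`` dosages in ``[0, 2]``.
    vntr_dosage : numpy.ndarray or None
        Count of long alleles per sample, entries in ``{0, 1, 2}``.  Absent
        for panels used only for LD or prediction.
    """

    sample_ids: list
    snp_ids: list
    effect_alleles: list
    genotypes: np.ndarray
    vntr_dosage: np.ndarray | None = None
    other_alleles: list | None = None
    source: str = ""

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.snp_ids = list(self.snp_ids)
        self.effect_alleles = [str(a) for a in self.effect_alleles]
        if self.other_alleles is not None:
            self.other_alleles = [str(a) for a in self.other_alleles]
        if self.vntr_dosage is not None:
            self.vntr_dosage = np.asarray(self.vntr_dosage, dtype=float)
        self.validate()

    def validate(self):
        n, m = self.genotypes.shape
        if n < 2 or m < 1:
            raise ValueError("panel needs at least 2 samples and 1 SNP")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.snp_ids) != m or len(self.effect_alleles) != m:
            raise ValueError("snp_ids/effect_alleles length does not match columns")
        if self.other_alleles is not None and len(self.other_alleles) != m:
            raise ValueError("other_alleles length does not match columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        if np.isnan(self.genotypes).any():
            raise ValueError("missing genotype entries; apply QC first")
        if self.genotypes.min() < 0 or self.genotypes.max() > 2:
            raise ValueError("genotype dosages must lie in [0, 2]")
        if self.vntr_dosage is not None:
            if self.vntr_dosage.shape != (n,):
                raise ValueError("vntr_dosage length does not match samples")
            if not np.isin(self.vntr_dosage, (0.0, 1.0, 2.0)).all():
                raise ValueError("vntr_dosage entries must be in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def normalized(self) -> np.ndarray:
        """Denominator-n normalized genotype matrix (see module docstring)."""
        return normalize_genotypes(self.genotypes, self.snp_ids)

    def subset_snps(self, snp_ids) -> "TagPanel":
        """Panel restricted to ``snp_ids`` in the given order."""
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return replace(
            self,
            snp_ids=[self.snp_ids[j] for j in idx],
            effect_alleles=[self.effect_alleles[j] for j in idx],
            other_alleles=(
                [self.other_alleles[j] for j in idx] if self.other_alleles else None
            ),
            genotypes=self.genotypes[:, idx],
        )

    def reorder_samples(self, sample_ids) -> "TagPanel":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            genotypes=self.genotypes[idx],
            vntr_dosage=None if self.vntr_dosage is None else self.vntr_dosage[idx],
        )
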