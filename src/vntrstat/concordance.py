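"""Method-concordance analysis: individual-level vs summary-statistics p-values.

Given paired association p-values for the same phenotypes from the
individual-level test (``P.g``) and the summary-statistics test (``P.s``),
this module reproduces the validation battery used to establish their
agreement: with ``y = -log10(P.g)`` and ``x = -log10(P.s)``, it reports
Pearson and Spearman correlations, ordinary least-squares fits in both
directions with coefficient standard errors, and a two-sample
Kolmogorov-Smirnov test of whether ``x`` and ``y`` share a distribution.

A 61-phenotype UK Biobank comparison table is packaged as a fixture
(p-values as printed, i.e. rounded) and loads with an integrity check.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FixtureError

__all__ = [
    "MethodComparison",
    "ConcordanceReport",
    "RegressionFit",
    "neglog10_transform",
    "concordance_stats",
    "load_table2_fixture",
]

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "table2_ukbb.tsv"
_FIXTURE_SHA256 = "37443116664a0eb28e5d99290685821f6ebb9a3f3cf92d195a83393a16798e14"


@dataclass
class MethodComparison:
    """Paired p-values from the two methods across phenotypes."""

    labels: list
    p_g: np.ndarray
    p_s: np.ndarray

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.p_g = np.asarray(self.p_g, dtype=float)
        self.p_s = np.asarray(self.p_s, dtype=float)
        n = len(self.labels)
        if n < 3:
            raise ValueError("need at least 3 phenotypes to compare")
        if self.p_g.shape != (n,) or self.p_s.shape != (n,):
            raise ValueError("p-value vectors must match labels length")
        if len(set(self.labels)) != n:
            raise ValueError("phenotype labels must be unique")
        for name, p in (("p_g", self.p_g), ("p_s", self.p_s)):
            if ((p <= 0) | (p > 1)).any():
                raise ValueError(f"{name} entries must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.labels)


def neglog10_transform(p, floor: float = 1e-300) -> np.ndarray:
    """Elementwise ``-log10(p)`` with clamping of underflowing p-values."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p < floor).any():
        warnings.warn(f"clamping {(p < floor).sum()} p-value(s) below {floor:g}")
        p = np.maximum(p, floor)
    return -np.log10(p)


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
        }


@dataclass
class ConcordanceReport:
    """Agreement statistics between the two -log10 p-value vectors."""

    n: int
    pearson_r: float
    spearman_rho: float
    fit_g_on_s: RegressionFit  # y = -log10(P.g) regressed on x = -log10(P.s)
    fit_s_on_g: RegressionFit  # x regressed on y
    ks_stat: float
    ks_p: float
    ks_method: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "fit_g_on_s": self.fit_g_on_s.to_dict(),
            "fit_s_on_g": self.fit_s_on_g.to_dict(),
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
            "ks_method": self.ks_method,
        }


def _ols(yy: np.ndarray, xx: np.ndarray) -> RegressionFit:
    fit = sm.OLS(yy, sm.add_constant(xx)).fit()
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        intercept_se=float(fit.bse[0]),
        slope_se=float(fit.bse[1]),
    )


def concordance_stats(
    cmp: MethodComparison,
    ks_method: str = "exact",
    p_floor: float = 1e-300,
) -> ConcordanceReport:
    """Full concordance battery on a method comparison.

    Spearman uses average ranks for ties (printed p-value tables contain
    many).  The KS test is the two-sample test between the ``x`` and ``y``
    vectors; the exact small-sample distribution is the default, matching
    common statistical practice at these sample sizes (``ks_method`` may
    be ``"asymp"``).
    """
    y = neglog10_transform(cmp.p_g, floor=p_floor)
    x = neglog10_transform(cmp.p_s, floor=p_floor)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a -log10 p-value vector")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    ks = stats.ks_2samp(x, y, method=ks_method)
    return ConcordanceReport(
        n=len(cmp),
        pearson_r=float(pearson.statistic),
        spearman_rho=float(spearman.statistic),
        fit_g_on_s=_ols(y, x),
        fit_s_on_g=_ols(x, y),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        ks_method=ks_method,
    )


def load_table2_fixture() -> MethodComparison:
    """Load the packaged 61-phenotype UK Biobank comparison table.

    Values are as printed in the source table (rounded); the file's SHA-256
    digest is verified before parsing.
    """
    ref = resources.files("vntrstat").joinpath("data", _FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureError(
            f"fixture {_FIXTURE_NAME} failed its checksum ({digest[:12]}...)"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t")
    cmp = MethodComparison(
        labels=df["phenotype"].tolist(),
        p_g=df["p_vntr_g"].to_numpy(),
        p_s=df["p_vntr_s"].to_numpy(),
    )
    if len(cmp) != 61:
        raise FixtureError(f"expected 61 phenotypes, found {len(cmp)}")
    return cmp
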