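"""Synthetic tag-SNP/VNTR panels and phenotypes.

The generator emulates the study design the association test assumes: a
biallelic VNTR (long/short alleles) in linkage disequilibrium with a set
of nearby tag SNPs, sampled in Hardy-Weinberg equilibrium, plus phenotypes
built from a configurable standardized VNTR effect, optional covariates,
and Gaussian noise scaled so ``var(Y) = 1``.

Default targets for the VNTR-SNP dosage correlations are the published LD
profile of the eight 5-HTTLPR tag SNPs (0.54, 0.37, 0.25, 0.10, -0.02,
0.04, -0.07, 0.17).  Tag-tag LD is not published for this locus, so the
default is an exchangeable correlation calibrated such that the implied
population prediction R^2 of the VNTR from the tags equals the reported
full-model accuracy of 0.85; a scalar or full matrix may be supplied
instead.

Two sampling mechanisms are available:

``"exact"`` (default)
    A haplotype distribution over all ``2**(m+1)`` haplotypes is solved by
    linear programming to match every allele frequency and every pairwise
    dosage correlation exactly at the population level; haplotypes are
    drawn i.i.d. and summed in pairs into dosages.  All quantities the
    association method depends on are functions of these first and second
    moments.

``"copula"``
    Gaussian-copula thresholding: one latent multivariate normal draw per
    haplotype, thresholded at each variant's frequency quantile.  The
    latent correlations are calibrated by numerically inverting the
    monotone latent-to-dosage correlation map.  The thresholding attenuates
    joint (not pairwise) structure, so very high multi-SNP prediction R^2
    targets are unreachable on this path; it remains useful when only
    marginal LD targets matter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, InfeasibleVarianceError
from .individual import PhenotypeData, marginal_gwas
from .panel import TagPanel
from .summary_assoc import SummaryStats

__all__ = [
    "TABLE1_SNPS",
    "TABLE1_VNTR_LD",
    "SimConfig",
    "calibrate_latent",
    "simulate_panel",
    "simulate_phenotype",
    "generate_study",
    "StudyBundle",
]

logger = logging.getLogger(__name__)

#: The eight published tag SNPs of the 5-HTTLPR locus (GRCh38 coordinates)
#: with their reported LD (dosage correlation) with the VNTR.
TABLE1_SNPS = (
    {"snp_id": "rs1487971", "chrom": "17", "pos": 30245735, "vntr_ld": 0.54},
    {"snp_id": "rs2129785", "chrom": "17", "pos": 30263512, "vntr_ld": 0.37},
    {"snp_id": "rs11651241", "chrom": "17", "pos": 30262460, "vntr_ld": 0.25},
    {"snp_id": "rs4794873", "chrom": "17", "pos": 30421334, "vntr_ld": 0.10},
    {"snp_id": "rs887469", "chrom": "17", "pos": 30365556, "vntr_ld": -0.02},
    {"snp_id": "rs1061342", "chrom": "17", "pos": 30787445, "vntr_ld": 0.04},
    {"snp_id": "rs4494608", "chrom": "17", "pos": 30161773, "vntr_ld": -0.07},
    {"snp_id": "rs7217677", "chrom": "17", "pos": 29448649, "vntr_ld": 0.17},
)

TABLE1_VNTR_LD = np.array([s["vntr_ld"] for s in TABLE1_SNPS])

# non-palindromic allele pairs cycled over simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class SimConfig:
    """Generative configuration for one synthetic study.

    Sample-count defaults mirror the reference study's cohorts: a training
    panel of 276 (the Dutch reference), an LD panel of 503 (European
    subjects of a public reference panel), and a GWAS cohort of 10,000.
    ``alpha`` is the VNTR effect on the standardized scale; covariate
    effects are per-covariate standardized effect sizes.  ``noise_sd`` is
    derived as ``sqrt(1 - alpha^2 - sum(effects^2))`` when not given, so
    ``var(Y) = 1``.
    """

    n_train: int = 276
    n_gwas: int = 10_000
    n_ld: int = 503
    snp_count: int = 8
    snp_freqs: np.ndarray | float = 0.5
    vntr_freq: float = 0.57
    target_vntr_ld: np.ndarray | None = None  # default: published profile
    tag_tag_ld: object = "auto"  # scalar | (m, m) matrix | named structure
    target_r2: float = 0.85
    alpha: float = 0.0
    covariate_effects: tuple = ()
    noise_sd: float | None = None
    mechanism: str = "exact"  # "exact" | "copula"
    seed: int | None = None

    def __post_init__(self):
        if self.snp_count < 1:
            raise ConfigError("snp_count must be >= 1")
        self.snp_freqs = np.broadcast_to(
            np.asarray(self.snp_freqs, dtype=float), (self.snp_count,)
        ).copy()
        if self.target_vntr_ld is None:
            if self.snp_count != len(TABLE1_VNTR_LD):
                raise ConfigError(
                    "target_vntr_ld required when snp_count != "
                    f"{len(TABLE1_VNTR_LD)}"
                )
            self.target_vntr_ld = TABLE1_VNTR_LD.copy()
        self.target_vntr_ld = np.asarray(self.target_vntr_ld, dtype=float)
        if self.target_vntr_ld.shape != (self.snp_count,):
            raise ConfigError("target_vntr_ld length must equal snp_count")
        freqs = np.concatenate([[self.vntr_freq], self.snp_freqs])
        if ((freqs <= 0) | (freqs >= 1)).any():
            raise ConfigError("all frequencies must lie in (0, 1)")
        if np.abs(self.target_vntr_ld).max(initial=0.0) >= 1:
            raise ConfigError("|target correlations| must be < 1")
        if self.mechanism not in ("exact", "copula"):
            raise ConfigError("mechanism must be 'exact' or 'copula'")
        if self.covariate_effects:
            self.covariate_effects = tuple(float(c) for c in self.covariate_effects)
        explained = self.alpha**2 + sum(c**2 for c in self.covariate_effects)
        if self.noise_sd is None:
            if explained > 1:
                raise InfeasibleVarianceError(
                    f"alpha^2 + covariate variance = {explained:.3f} > 1"
                )
        elif self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")

    # -- derived structure ---------------------------------------------------

    def snp_ids(self) -> list:
        if self.snp_count == len(TABLE1_SNPS) and np.array_equal(
            self.target_vntr_ld, TABLE1_VNTR_LD
        ):
            return [s["snp_id"] for s in TABLE1_SNPS]
        return [f"snp{j + 1}" for j in range(self.snp_count)]

    def allele_pairs(self) -> list:
        return [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(self.snp_count)]

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        explained = self.alpha**2 + sum(c**2 for c in self.covariate_effects)
        return float(np.sqrt(1.0 - explained))

    def tag_tag_matrix(self) -> np.ndarray:
        """Resolved dosage-scale tag-tag correlation targets.

        Named structures: ``"calibrated"`` — exchangeable correlation solved
        so the implied population prediction R^2 equals ``target_r2``
        (requires the exact mechanism); ``"onefactor"`` — correlations
        induced by a single latent factor (the VNTR's own latent), feasible
        under the copula by construction.  ``"auto"`` picks per mechanism.
        """
        m = self.snp_count
        tt = self.tag_tag_ld
        if isinstance(tt, str):
            if tt == "auto":
                tt = "calibrated" if self.mechanism == "exact" else "onefactor"
            if tt == "calibrated":
                rho = _calibrate_exchangeable(self.target_vntr_ld, self.target_r2)
                out = np.full((m, m), rho)
            elif tt == "onefactor":
                out = self._onefactor_tag_tag()
            else:
                raise ConfigError(f"unknown tag_tag_ld mode {tt!r}")
        elif np.isscalar(tt):
            out = np.full((m, m), float(tt))
        else:
            out = np.asarray(tt, dtype=float)
            if out.shape != (m, m):
                raise ConfigError("tag_tag_ld matrix must be (snp_count, snp_count)")
            if not np.allclose(out, out.T, atol=1e-10):
                raise ConfigError("tag_tag_ld matrix must be symmetric")
        np.fill_diagonal(out, 1.0)
        return out

    def _onefactor_tag_tag(self) -> np.ndarray:
        """Tag-tag dosage correlations induced by the VNTR's latent factor.

        Each SNP's latent is ``l_j * F + sqrt(1 - l_j^2) * e_j`` with ``F``
        the VNTR latent and ``l_j`` calibrated to the marginal target, so
        the latent tag-tag correlation is ``l_j * l_k`` and the full latent
        matrix is positive semidefinite by construction.
        """
        m = self.snp_count
        lat = np.array(
            [
                _latent_for_target(self.target_vntr_ld[j], self.vntr_freq,
                                   self.snp_freqs[j])
                for j in range(m)
            ]
        )
        out = np.eye(m)
        for j in range(m):
            for k in range(j + 1, m):
                out[j, k] = out[k, j] = dosage_corr_from_latent(
                    lat[j] * lat[k], self.snp_freqs[j], self.snp_freqs[k]
                )
        return out

    def target_matrix(self) -> np.ndarray:
        """(m+1) x (m+1) dosage-correlation target; index 0 is the VNTR."""
        m = self.snp_count
        c = np.empty((m + 1, m + 1))
        c[0, 0] = 1.0
        c[0, 1:] = c[1:, 0] = self.target_vntr_ld
        c[1:, 1:] = self.tag_tag_matrix()
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ConfigError(
                "target correlation matrix (VNTR + tags) is not positive "
                "semidefinite"
            )
        return c

    def frequencies(self) -> np.ndarray:
        return np.concatenate([[self.vntr_freq], self.snp_freqs])


def _implied_r2(vntr_ld: np.ndarray, rho: float) -> float:
    m = len(vntr_ld)
    r = np.full((m, m), rho)
    np.fill_diagonal(r, 1.0)
    return float(vntr_ld @ np.linalg.solve(r, vntr_ld))


def _calibrate_exchangeable(vntr_ld: np.ndarray, target_r2: float) -> float:
    """Exchangeable tag-tag correlation whose implied prediction R^2 hits target.

    The map rho -> R^2 is U-shaped on the positive-definite range (it
    diverges at both boundaries), so the target is solved on the left,
    negative-rho branch: mutually anticorrelated tags jointly explain more
    of the VNTR than their marginal correlations suggest, which is the
    haplotype-structure regime consistent with a high reported full-model
    accuracy alongside modest marginal LD.
    """
    m = len(vntr_ld)
    if m == 1:
        return 0.0
    lo = -1.0 / (m - 1) + 1e-6
    hi = 0.999
    f = lambda rho: _implied_r2(vntr_ld, rho) - target_r2
    opt = optimize.minimize_scalar(
        lambda rho: _implied_r2(vntr_ld, rho), bounds=(lo, hi), method="bounded"
    )
    if f(opt.x) > 0:
        raise ConfigError(
            f"target_r2={target_r2} below the attainable minimum "
            f"{_implied_r2(vntr_ld, float(opt.x)):.3f} for this LD profile"
        )
    return float(optimize.brentq(f, lo, float(opt.x), xtol=1e-10))


# -- Gaussian-copula machinery ----------------------------------------------


def _bivariate_cdf(t1: float, t2: float, rho: float) -> float:
    return float(
        stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
    )


def dosage_corr_from_latent(rho: float, f1: float, f2: float) -> float:
    """Dosage-scale correlation implied by latent correlation ``rho``.

    Alleles are Bernoulli indicators of a latent Gaussian falling below the
    frequency quantile; dosages sum two i.i.d. haplotypes, so the dosage
    correlation equals the per-haplotype Bernoulli correlation.
    """
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    p11 = _bivariate_cdf(t1, t2, rho)
    return (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))


def max_attainable_corr(f1: float, f2: float) -> tuple:
    """Frechet bounds on the Bernoulli (dosage) correlation for two frequencies."""
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    hi = (min(f1, f2) - f1 * f2) / denom
    lo = (max(0.0, f1 + f2 - 1.0) - f1 * f2) / denom
    return lo, hi


def _latent_for_target(target: float, f1: float, f2: float) -> float:
    if abs(target) < 1e-12:
        return 0.0
    lo, hi = max_attainable_corr(f1, f2)
    if not lo < target < hi:
        raise ConfigError(
            f"target correlation {target:.3f} outside the attainable range "
            f"({lo:.3f}, {hi:.3f}) for frequencies {f1:.3f}, {f2:.3f}"
        )
    return float(
        optimize.brentq(
            lambda r: dosage_corr_from_latent(r, f1, f2) - target,
            -0.99999,
            0.99999,
            xtol=1e-10,
        )
    )


_latent_cache: dict = {}


def calibrate_latent(config: SimConfig) -> np.ndarray:
    """Latent (m+1)-dimensional correlation matrix for the copula mechanism.

    Each pairwise latent correlation is found by inverting the monotone
    latent-to-dosage map with Brent's method; results are cached per
    (frequencies, targets) key.  A non-PSD latent matrix — targets that are
    jointly unreachable under thresholding — raises :class:`ConfigError`
    before any sampling.
    """
    c = config.target_matrix()
    freqs = config.frequencies()
    key = (freqs.round(12).tobytes(), c.round(12).tobytes())
    cached = _latent_cache.get(key)
    if cached is not None:
        return cached.copy()
    d = len(freqs)
    latent = np.eye(d)
    for j in range(d):
        for k in range(j + 1, d):
            latent[j, k] = latent[k, j] = _latent_for_target(
                c[j, k], freqs[j], freqs[k]
            )
    if np.linalg.eigvalsh(latent).min() < -1e-8:
        raise ConfigError(
            "calibrated latent correlation matrix is not positive semidefinite: "
            "the pairwise targets are jointly unreachable under the Gaussian "
            "copula; relax tag_tag_ld/target_r2 or use mechanism='exact'"
        )
    _latent_cache[key] = latent.copy()
    return latent


# -- exact haplotype-distribution machinery ----------------------------------

_pool_cache: dict = {}


def haplotype_pool(config: SimConfig) -> tuple:
    """Haplotype distribution matching all first and second moments exactly.

    Solves a linear program for probabilities over the ``2**(m+1)``
    haplotypes (VNTR allele + m SNP alleles) subject to every allele
    frequency and every pairwise co-occurrence implied by the target
    dosage correlations.  Returns ``(atoms, probs)`` with ``atoms`` of
    shape ``(2**(m+1), m+1)``.
    """
    c = config.target_matrix()
    freqs = config.frequencies()
    key = (freqs.round(12).tobytes(), c.round(12).tobytes())
    cached = _pool_cache.get(key)
    if cached is not None:
        return cached
    d = len(freqs)
    if d > 16:
        raise ConfigError("exact mechanism supports at most 15 SNPs; use 'copula'")
    atoms = np.array(list(itertools.product((0.0, 1.0), repeat=d)))
    sd = np.sqrt(freqs * (1 - freqs))
    rows = [np.ones(len(atoms))]
    rhs = [1.0]
    for j in range(d):
        rows.append(atoms[:, j])
        rhs.append(freqs[j])
    for j in range(d):
        for k in range(j + 1, d):
            rows.append(atoms[:, j] * atoms[:, k])
            rhs.append(c[j, k] * sd[j] * sd[k] + freqs[j] * freqs[k])
    res = optimize.linprog(
        np.zeros(len(atoms)),
        A_eq=np.asarray(rows),
        b_eq=np.asarray(rhs),
        bounds=(0.0, 1.0),
        method="highs",
    )
    if res.status != 0:
        raise ConfigError(
            "no haplotype distribution matches the target moments exactly "
            f"({res.message}); use mechanism='copula' or relax the targets"
        )
    probs = np.clip(res.x, 0.0, None)
    probs = probs / probs.sum()
    _pool_cache[key] = (atoms, probs)
    return atoms, probs


# -- sampling -----------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ConfigError("a seed is mandatory for every stochastic call")
    return np.random.default_rng(seed)


def simulate_panel(
    config: SimConfig,
    n: int,
    seed,
    include_vntr: bool = True,
    sample_prefix: str = "S",
) -> TagPanel:
    """Draw ``n`` diploid samples: two i.i.d. haplotypes summed to dosages.

    Byte-identical output under a fixed seed.  ``include_vntr=False``
    yields a panel suitable only for LD or prediction.
    """
    rng = _rng(seed)
    d = config.snp_count + 1
    if config.mechanism == "copula":
        latent = calibrate_latent(config)
        chol = np.linalg.cholesky(
            latent + 1e-12 * np.eye(d)
        )
        thr = stats.norm.ppf(config.frequencies())
        dosage = np.zeros((n, d))
        for _ in range(2):
            z = rng.standard_normal((n, d)) @ chol.T
            dosage += z < thr
    else:
        atoms, probs = haplotype_pool(config)
        idx = rng.choice(len(atoms), size=(n, 2), p=probs)
        dosage = atoms[idx[:, 0]] + atoms[idx[:, 1]]
    pairs = config.allele_pairs()
    return TagPanel(
        sample_ids=[f"{sample_prefix}{i + 1:06d}" for i in range(n)],
        snp_ids=config.snp_ids(),
        effect_alleles=[p[0] for p in pairs],
        other_alleles=[p[1] for p in pairs],
        genotypes=dosage[:, 1:],
        vntr_dosage=dosage[:, 0] if include_vntr else None,
        source=f"simulated ({config.mechanism})",
    )


def simulate_phenotype(panel: TagPanel, config: SimConfig, seed) -> PhenotypeData:
    """Phenotype ``Y = alpha * std(G) + covariate effects + noise``.

    The VNTR dosage is standardized by its population moments
    (``mean 2f``, ``var 2f(1-f)``) so ``alpha`` is exactly the effect per
    population standard deviation; covariates are standard normal draws;
    the noise standard deviation is scaled so ``var(Y) = 1`` in
    expectation.
    """
    if panel.vntr_dosage is None:
        raise ValueError("panel has no VNTR dosages")
    rng = _rng(seed)
    n = panel.n_samples
    f = config.vntr_freq
    g_std = (panel.vntr_dosage - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    y = config.alpha * g_std
    k = len(config.covariate_effects)
    covs = None
    if k:
        covs = rng.standard_normal((n, k))
        y = y + covs @ np.asarray(config.covariate_effects)
    y = y + config.resolved_noise_sd() * rng.standard_normal(n)
    return PhenotypeData(
        sample_ids=list(panel.sample_ids),
        y=y,
        covariates=covs,
        covariate_names=[f"cov{i + 1}" for i in range(k)] if k else None,
    )


@dataclass
class StudyBundle:
    """One end-to-end synthetic study: train / LD / GWAS cohorts."""

    config: SimConfig
    train_panel: TagPanel
    ld_panel: TagPanel
    gwas_panel: TagPanel
    phenotype: PhenotypeData
    sumstats: SummaryStats
    seed: int = 0
    manifest: dict = field(default_factory=dict)


def generate_study(config: SimConfig) -> StudyBundle:
    """Generate three independent cohorts from one generative law.

    The training panel carries VNTR dosages (for weight fitting), the LD
    panel does not (reference-panel realism), and the GWAS cohort yields a
    phenotype plus marginal summary statistics via :func:`marginal_gwas`.
    Cohort seeds are spawned deterministically from ``config.seed``.
    """
    if config.seed is None:
        raise ConfigError("config.seed is mandatory for generate_study")
    ss = np.random.SeedSequence(config.seed)
    s_train, s_ld, s_gwas, s_pheno = ss.spawn(4)
    train = simulate_panel(config, config.n_train, s_train, sample_prefix="TR")
    ldp = simulate_panel(
        config, config.n_ld, s_ld, include_vntr=False, sample_prefix="LD"
    )
    gwas = simulate_panel(config, config.n_gwas, s_gwas, sample_prefix="GW")
    pheno = simulate_phenotype(gwas, config, s_pheno)
    sumstats = marginal_gwas(gwas, pheno)
    manifest = {
        "seed": int(config.seed),
        "mechanism": config.mechanism,
        "n_train": config.n_train,
        "n_ld": config.n_ld,
        "n_gwas": config.n_gwas,
        "alpha": config.alpha,
        "vntr_freq": config.vntr_freq,
        "snp_freqs": config.snp_freqs.tolist(),
        "target_vntr_ld": config.target_vntr_ld.tolist(),
        "tag_tag_ld": (
            "calibrated exchangeable (invented structure; tag-tag LD is not "
            "published for this locus)"
            if isinstance(config.tag_tag_ld, str)
            else np.asarray(config.tag_tag_ld).tolist()
        ),
        "covariate_effects": list(config.covariate_effects),
        "noise_sd": config.resolved_noise_sd(),
    }
    return StudyBundle(
        config=config,
        train_panel=train,
        ld_panel=ldp,
        gwas_panel=gwas,
        phenotype=pheno,
        sumstats=sumstats,
        seed=int(config.seed),
        manifest=manifest,
    )
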