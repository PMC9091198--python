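"""Simulation experiments validating the summary-statistics test.

These are the package's standard self-checks, mirroring the validation
logic of the method: algebraic equivalence of the summary and
individual-level statistics on one cohort, type-I error calibration under
the null, recovery of a nonzero standardized VNTR effect, and fidelity of
the simulator's realized LD to its targets.  Each experiment is a plain
function returning a dict of numbers, so the same code backs the test
suite and reproducibility scripts.
"""

from __future__ import annotations

import numpy as np

from .individual import marginal_gwas, run_vntr_g
from .ld import compute_ld
from .prediction import fit_prediction_weights, predict_vntr_dosage, vntr_tag_ld
from .simulate import SimConfig, generate_study, simulate_panel, simulate_phenotype
from .summary_assoc import test_summary, vntr_s_zscore

__all__ = [
    "zscore_equivalence",
    "null_rejection_rate",
    "alpha_recovery",
    "ld_fidelity",
]


def zscore_equivalence(
    n_gwas: int = 10_000, alpha: float = 0.1, seed: int = 0
) -> dict:
    """Summary vs individual Z on one cohort.

    With the LD matrix computed from the GWAS sample itself (denominator-n)
    and marginal Z defined as ``sqrt(n) * corr(x_j, Y)``, the combined
    summary Z equals ``sqrt(n) * corr(G_hat, Y)`` as an algebraic identity;
    with OLS t-statistics instead, agreement is approximate with an
    O(1/n) finite-sample degrees-of-freedom gap.

    Returns ``exact_abs_diff``, ``t_rel_diff``, and the Z values.
    """
    cfg = SimConfig(seed=seed, alpha=alpha, n_gwas=n_gwas)
    bundle = generate_study(cfg)
    model = fit_prediction_weights(bundle.train_panel)
    panel = bundle.gwas_panel
    y = bundle.phenotype.y
    n = panel.n_samples
    v_sample = compute_ld(panel).values

    # exact route: z_j = sqrt(n) * corr(x_j, Y); beta of the marginal scan
    # already equals that correlation on the normalized scale
    z_exact = np.sqrt(n) * bundle.sumstats.beta
    z_summary = vntr_s_zscore(model.weights, z_exact, v_sample)
    g_hat = predict_vntr_dosage(model, panel)
    z_individual = float(np.sqrt(n) * np.corrcoef(g_hat, y)[0, 1])

    # t-statistic route against the joint individual-level regression
    z_summary_t = vntr_s_zscore(model.weights, bundle.sumstats.z, v_sample)
    res_g = run_vntr_g(model, panel, bundle.phenotype)

    return {
        "n": n,
        "z_summary_exact": z_summary,
        "z_individual_exact": z_individual,
        "exact_abs_diff": abs(z_summary - z_individual),
        "z_summary_t": z_summary_t,
        "z_individual_t": res_g.z_alpha,
        "t_rel_diff": abs(z_summary_t - res_g.z_alpha) / abs(res_g.z_alpha),
    }


def null_rejection_rate(
    n_reps: int = 2000,
    n_gwas: int = 2000,
    level: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the summary test under ``alpha = 0``.

    Prediction weights are fitted once on a training panel; each replicate
    draws a fresh GWAS cohort and null phenotype, runs the marginal scan,
    estimates LD from the same cohort, and applies the full summary test.
    """
    cfg = SimConfig(seed=seed, alpha=0.0, n_gwas=n_gwas)
    ss = np.random.SeedSequence(seed)
    s_train, s_reps = ss.spawn(2)
    train = simulate_panel(cfg, cfg.n_train, s_train, sample_prefix="TR")
    model = fit_prediction_weights(train)
    rejections = 0
    for child in s_reps.spawn(n_reps):
        s_panel, s_pheno = child.spawn(2)
        panel = simulate_panel(cfg, n_gwas, s_panel)
        pheno = simulate_phenotype(panel, cfg, s_pheno)
        stats = marginal_gwas(panel, pheno)
        v = compute_ld(panel)
        res = test_summary(model, stats, v)
        if res.p_value < level:
            rejections += 1
    return {
        "n_reps": n_reps,
        "n_gwas": n_gwas,
        "level": level,
        "rejections": rejections,
        "rate": rejections / n_reps,
    }


def alpha_recovery(
    n_reps: int = 200,
    n_gwas: int = 20_000,
    alpha: float = 0.1,
    oracle_n: int = 500_000,
    seed: int = 0,
) -> dict:
    """Mean recovered effect vs a large-sample oracle of the attenuated truth.

    The estimator targets the effect of the *predicted* dosage, which is an
    imperfect proxy for the true VNTR dosage, so the recovered effect is the
    true standardized ``alpha`` shrunk by the prediction quality.  A single
    very large cohort run with the same fixed weights provides the
    attenuated reference value; the replicate mean should match it within
    combined Monte-Carlo error.
    """
    cfg = SimConfig(seed=seed, alpha=alpha, n_gwas=n_gwas)
    ss = np.random.SeedSequence(seed)
    s_train, s_oracle, s_reps = ss.spawn(3)
    train = simulate_panel(cfg, cfg.n_train, s_train, sample_prefix="TR")
    model = fit_prediction_weights(train)

    def one_alpha(n, child):
        s_panel, s_pheno = child.spawn(2)
        panel = simulate_panel(cfg, n, s_panel)
        pheno = simulate_phenotype(panel, cfg, s_pheno)
        stats = marginal_gwas(panel, pheno)
        v = compute_ld(panel)
        return test_summary(model, stats, v), panel

    oracle_res, _ = one_alpha(oracle_n, s_oracle)
    estimates = np.array(
        [one_alpha(n_gwas, child)[0].alpha_hat for child in s_reps.spawn(n_reps)]
    )
    mc_se = estimates.std(ddof=1) / np.sqrt(n_reps)
    return {
        "n_reps": n_reps,
        "n_gwas": n_gwas,
        "true_alpha": alpha,
        "mean_alpha_hat": float(estimates.mean()),
        "mc_se": float(mc_se),
        "oracle_alpha": oracle_res.alpha_hat,
        "oracle_se": oracle_res.se_alpha,
        "combined_se": float(np.sqrt(mc_se**2 + oracle_res.se_alpha**2)),
    }


def ld_fidelity(n: int = 5000, seed: int = 0, config: SimConfig | None = None) -> dict:
    """Realized VNTR-tag dosage correlations vs the configured targets."""
    cfg = config if config is not None else SimConfig(seed=seed)
    panel = simulate_panel(cfg, n, seed)
    realized = vntr_tag_ld(panel)
    err = np.abs(realized - cfg.target_vntr_ld)
    return {
        "n": n,
        "targets": cfg.target_vntr_ld.tolist(),
        "realized": realized.tolist(),
        "max_abs_error": float(err.max()),
    }
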