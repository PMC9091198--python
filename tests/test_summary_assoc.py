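import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vntrstat.errors import (
    AlleleMismatchError,
    DegenerateWeightsError,
    NoUsableSNPsError,
    VntrStatError,
)
from vntrstat.individual import marginal_gwas
from vntrstat.ld import LDMatrix, compute_ld
from vntrstat.panel import normalize_genotypes
from vntrstat.prediction import fit_prediction_weights
from vntrstat.summary_assoc import (
    SummaryStats,
    alpha_variance,
    estimate_alpha,
    harmonize,
    vntr_s_zscore,
    zscore_to_pvalue,
)
from vntrstat.summary_assoc import test_summary as run_summary_test

from conftest import random_panel


def make_stats(snp_ids, z=None, beta=None, se=None, n=1000, eff=None, oth=None):
    m = len(snp_ids)
    return SummaryStats(
        snp_ids=list(snp_ids),
        effect_alleles=eff or ["A"] * m,
        other_alleles=oth or ["G"] * m,
        n=np.full(m, float(n)),
        beta=beta,
        se=se,
        z=z,
    )


class TestEstimateAlpha:
    def test_single_snp_identity(self):
        assert estimate_alpha([1.0], [0.2], [[1.0]]) == pytest.approx(0.2)

    def test_weight_orthogonal_to_signal(self):
        assert estimate_alpha([1.0, 0.0], [0.0, 0.3], np.eye(2)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_matches_individual_level_ols_oracle(self, seed):
        # alpha from summary pieces == OLS of Y on the weighted score when V
        # comes from the same sample (denominator-n throughout)
        rng = np.random.default_rng(seed)
        panel = random_panel(seed, n=200, m=3)
        y = rng.standard_normal(200)
        x = normalize_genotypes(panel.genotypes)
        n = 200
        w = rng.standard_normal(3)
        v = compute_ld(panel).values
        betas = x.T @ (y - y.mean()) / (n * y.std())
        alpha_summary = estimate_alpha(w, betas, v)
        score = x @ w
        yn = (y - y.mean()) / y.std()
        alpha_ols = float(score @ yn / (score @ score))
        assert alpha_summary == pytest.approx(alpha_ols, abs=1e-8)

    def test_degenerate_weights(self):
        with pytest.raises(DegenerateWeightsError):
            estimate_alpha([0.0, 0.0], [0.1, 0.1], np.eye(2))


class TestAlphaVariance:
    def test_closed_form(self):
        var, k = alpha_variance([1.0], [[1.0]], n=100)
        assert var == pytest.approx(0.01)
        assert k == pytest.approx(1.0)

    def test_inverse_n_scaling(self):
        v1, _ = alpha_variance([1.0, 0.5], np.eye(2), n=500)
        v2, _ = alpha_variance([1.0, 0.5], np.eye(2), n=1000)
        assert v1 == pytest.approx(2 * v2)

    def test_correlated_pair(self):
        v_ld = np.array([[1.0, 0.5], [0.5, 1.0]])
        var, k = alpha_variance([1.0, 1.0], v_ld, n=300)
        assert k == pytest.approx(3.0)
        assert var == pytest.approx(1.0 / 900.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            alpha_variance([1.0], [[1.0]], n=-5)
        with pytest.raises(ValueError):
            alpha_variance([1.0], [[1.0]], n=10, sigma2_y=0.0)


class TestZScore:
    def test_single_snp_passthrough(self):
        assert vntr_s_zscore([1.0], [2.5], [[1.0]]) == pytest.approx(2.5)

    def test_correlated_pair_closed_form(self):
        v = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert vntr_s_zscore([1.0, 1.0], [1.0, 1.0], v) == pytest.approx(
            2.0 / np.sqrt(3.0)
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance_and_sign_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(4)
        z = rng.standard_normal(4)
        panel = random_panel(seed % 100, n=50, m=4)
        v = compute_ld(panel).values
        base = vntr_s_zscore(w, z, v)
        assert vntr_s_zscore(c * w, z, v) == pytest.approx(base, rel=1e-9)
        assert vntr_s_zscore(-w, z, v) == pytest.approx(-base, rel=1e-9)

    def test_snp_reordering_invariance(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(4)
        z = rng.standard_normal(4)
        v = compute_ld(random_panel(5, n=60, m=4)).values
        perm = rng.permutation(4)
        assert vntr_s_zscore(w[perm], z[perm], v[np.ix_(perm, perm)]) == pytest.approx(
            vntr_s_zscore(w, z, v), rel=1e-10
        )


class TestPValue:
    def test_null_statistic(self):
        assert zscore_to_pvalue(0.0) == pytest.approx(1.0)

    def test_matches_normal_quantile(self):
        assert zscore_to_pvalue(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_genome_wide_threshold_crossing(self):
        # |z| ~ 5.4513 is the two-sided normal quantile of p = 5e-8
        assert zscore_to_pvalue(5.4513) == pytest.approx(5e-8, rel=1e-3)
        assert zscore_to_pvalue(5.46) < 5e-8 < zscore_to_pvalue(5.44)


class TestSummaryStatsValidation:
    def test_z_derived_from_beta_se(self):
        s = make_stats(["a"], beta=np.array([0.2]), se=np.array([0.1]))
        assert s.z[0] == pytest.approx(2.0)

    def test_inconsistent_beta_se_z_rejected(self):
        with pytest.raises(VntrStatError, match="disagrees"):
            make_stats(["a"], beta=np.array([0.2]), se=np.array([0.1]),
                       z=np.array([3.0]))

    def test_needs_some_effect_representation(self):
        with pytest.raises(ValueError):
            make_stats(["a"])


class TestHarmonize:
    def test_identity_inputs_unchanged(self, study, study_model):
        v = compute_ld(study.ld_panel)
        s, m, vv = harmonize(study.sumstats, study_model, v)
        np.testing.assert_array_equal(s.z, study.sumstats.z)
        np.testing.assert_array_equal(m.weights, study_model.weights)
        np.testing.assert_allclose(vv.values, v.values, atol=1e-12)

    def test_swapped_alleles_flip_sign(self, study, study_model):
        st_ = study.sumstats
        eff = list(st_.effect_alleles)
        oth = list(st_.other_alleles)
        eff[0], oth[0] = oth[0], eff[0]
        beta = st_.beta.copy()
        beta[0] *= -1
        z = st_.z.copy()
        z[0] *= -1
        swapped = SummaryStats(st_.snp_ids, eff, oth, st_.n, beta=beta,
                               se=st_.se, z=z)
        v = compute_ld(study.ld_panel)
        s, m, vv = harmonize(swapped, study_model, v)
        # flipped back: identical to harmonizing the original
        np.testing.assert_allclose(s.z, study.sumstats.z, atol=1e-12)
        np.testing.assert_allclose(vv.values, v.values, atol=1e-12)

    def test_ld_panel_coded_by_other_allele_is_sign_flipped(self, study, study_model):
        # an LD matrix estimated on a panel coding the opposite allele of
        # one SNP carries its own orientation; harmonization must flip its
        # row/column so the combined Z is invariant to the LD panel coding
        from vntrstat.panel import TagPanel

        p = study.ld_panel
        geno = p.genotypes.copy()
        geno[:, 0] = 2.0 - geno[:, 0]
        eff = list(p.effect_alleles)
        oth = list(p.other_alleles)
        eff[0], oth[0] = oth[0], eff[0]
        recoded = TagPanel(p.sample_ids, p.snp_ids, eff, geno, other_alleles=oth)
        v_recoded = compute_ld(recoded)
        v = compute_ld(p)
        _, _, v1 = harmonize(study.sumstats, study_model, v)
        _, _, v2 = harmonize(study.sumstats, study_model, v_recoded)
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-12)
        r1 = run_summary_test(study_model, study.sumstats, v)
        r2 = run_summary_test(study_model, study.sumstats, v_recoded)
        assert r1.z_alpha == pytest.approx(r2.z_alpha, rel=1e-12)

    def test_seven_of_eight_snps_subsets_model(self, study, study_model):
        st_ = study.sumstats.subset([s for s in study.sumstats.snp_ids
                                     if s != "rs1061342"])
        v = compute_ld(study.ld_panel)
        s, m, vv = harmonize(st_, study_model, v)
        assert m.n_snps == 7
        assert m.dropped_snps == ["rs1061342"]
        assert len(vv.snp_ids) == 7

    def test_irreconcilable_alleles_named(self, study, study_model):
        st_ = study.sumstats
        eff = list(st_.effect_alleles)
        eff[2] = "C" if eff[2] in ("A", "G") else "A"
        oth = list(st_.other_alleles)
        oth[2] = "A" if eff[2] == "C" else "C"
        bad = SummaryStats(st_.snp_ids, eff, oth, st_.n, z=st_.z)
        with pytest.raises(AlleleMismatchError, match=st_.snp_ids[2]):
            harmonize(bad, study_model, compute_ld(study.ld_panel))

    def test_empty_intersection(self, study, study_model):
        st_ = study.sumstats
        renamed = SummaryStats([f"x{s}" for s in st_.snp_ids], st_.effect_alleles,
                               st_.other_alleles, st_.n, z=st_.z)
        with pytest.raises(NoUsableSNPsError):
            harmonize(renamed, study_model, compute_ld(study.ld_panel))


class TestTestSummary:
    def test_power_at_strong_effect(self, study, study_model):
        v = compute_ld(study.gwas_panel)
        res = run_summary_test(study_model, study.sumstats, v)
        assert res.p_value < 5e-8
        assert res.k_wv > 0
        assert 0 < res.p_value <= 1

    def test_z_supplied_directly_equals_derived(self, study, study_model):
        st_ = study.sumstats
        z_only = SummaryStats(st_.snp_ids, st_.effect_alleles, st_.other_alleles,
                              st_.n, z=st_.z)
        v = compute_ld(study.ld_panel)
        r1 = run_summary_test(study_model, st_, v)
        r2 = run_summary_test(study_model, z_only, v)
        assert r1.z_alpha == pytest.approx(r2.z_alpha, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_heterogeneous_n_collapsed_to_median(self, study, study_model):
        st_ = study.sumstats
        n = st_.n.copy()
        n[0] = n[0] * 2
        het = SummaryStats(st_.snp_ids, st_.effect_alleles, st_.other_alleles,
                           n, beta=st_.beta, se=st_.se, z=st_.z)
        res = run_summary_test(study_model, het, compute_ld(study.ld_panel))
        assert res.n_used == pytest.approx(np.median(n))

    def test_zalpha_consistency_invariant(self, study, study_model):
        # z_alpha^2 == alpha_hat^2 / var_alpha * (sigma2_y scaling) when
        # alpha is estimated from betas on the same n
        res = run_summary_test(study_model, study.sumstats,
                           compute_ld(study.gwas_panel), epsilon=0.0)
        z_from_alpha = res.alpha_hat / np.sqrt(res.var_alpha)
        assert res.z_alpha**2 == pytest.approx(z_from_alpha**2, rel=2e-2)

    def test_power_monotone_in_effect_and_sample_size(self):
        # mean chi-square statistic grows with |alpha| and with n
        # (sampling-error tolerant: 25 replicates per grid cell)
        from vntrstat.individual import marginal_gwas
        from vntrstat.simulate import SimConfig, simulate_panel, simulate_phenotype

        def mean_chi2(alpha, n_gwas, base_seed):
            cfg = SimConfig(seed=0, alpha=alpha, n_gwas=n_gwas)
            train = simulate_panel(cfg, cfg.n_train, seed=99, sample_prefix="TR")
            model = fit_prediction_weights(train)
            vals = []
            for r in range(25):
                panel = simulate_panel(cfg, n_gwas, seed=base_seed + r)
                pheno = simulate_phenotype(panel, cfg, seed=base_seed + 10_000 + r)
                stats = marginal_gwas(panel, pheno)
                v = compute_ld(panel)
                vals.append(run_summary_test(model, stats, v).z_alpha ** 2)
            return np.mean(vals)

        by_alpha = [mean_chi2(a, 2000, 300) for a in (0.0, 0.05, 0.1)]
        assert by_alpha[0] < by_alpha[1] < by_alpha[2]
        by_n = [mean_chi2(0.05, n, 600) for n in (1000, 4000)]
        assert by_n[0] < by_n[1]

    def test_shrinkage_flag_recorded(self, study, study_model):
        res = run_summary_test(study_model, study.sumstats,
                           compute_ld(study.ld_panel), epsilon=0.01)
        assert res.mode_flags["epsilon"] == pytest.approx(0.01)
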