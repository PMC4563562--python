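"""AI-REML: likelihood correctness, recovery, partitioning, attribution."""

import numpy as np
import pytest

from liabherit import (
    GenoSimConfig,
    assign_liability_phenotypes,
    compute_grm,
    fit_joint_chromosomes,
    fit_reml,
    per_chromosome_grms,
    per_snp_variance,
    phenotype_frame,
    restricted_loglik,
    simulate_genotypes,
    stratified_fit,
)
from liabherit.errors import InvalidInputError

from _oracles import dense_restricted_loglik


def _sim_quantitative(seed, n=400, m=300, h2=0.4, n_chrom=1):
    cfg = GenoSimConfig(
        n_snps=m, n_causal=max(10, m // 10), h2_liab=h2, prevalence_K=0.5,
        n_chromosomes=n_chrom, seed=seed,
    )
    g = simulate_genotypes(cfg, n_samples=n)
    f = phenotype_frame(assign_liability_phenotypes(g, cfg))
    return g, f["liability"].to_numpy()


class TestLikelihood:
    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (5, 2)])
    def test_matches_dense_oracle_at_fixed_parameters(self, n, seed):
        rng = np.random.default_rng(seed)
        B = rng.normal(size=(n, n))
        A = B @ B.T / n
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        for sg, se_ in [(0.5, 0.7), (1.2, 0.1), (0.01, 2.0)]:
            ours = restricted_loglik(y, X, [A], [sg], se_)
            oracle = dense_restricted_loglik(y, X, sg * A + se_ * np.eye(n))
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_loglik_at_fit_agrees_between_backends(self):
        g, y = _sim_quantitative(5, n=150, m=100)
        grm = compute_grm(g)
        fit = fit_reml(y, None, [grm])  # eigen backend
        direct = restricted_loglik(
            y, np.ones((150, 1)), [grm], fit.sigma2, fit.sigma2_e
        )
        assert fit.loglik == pytest.approx(direct, abs=1e-6)


class TestFitReml:
    def test_recovers_h2_small_scale(self):
        ests, ses = [], []
        for seed in range(3):
            g, y = _sim_quantitative(seed, n=600, m=400, h2=0.4)
            fit = fit_reml(y, None, [compute_grm(g)])
            assert fit.converged
            ests.append(fit.h2_obs_total)
            ses.append(fit.h2_total_se)
        ests = np.array(ests)
        assert np.all(np.abs(ests - 0.4) < 2.5 * np.array(ses))

    def test_identity_grm_flagged_unidentifiable(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=120)
        fit = fit_reml(y, None, [np.eye(120)])
        assert not fit.identifiable

    def test_invariant_to_consistent_reordering(self):
        g, y = _sim_quantitative(9, n=200, m=150)
        grm = compute_grm(g)
        fit = fit_reml(y, None, [grm])
        perm = np.random.default_rng(0).permutation(200)
        fit2 = fit_reml(y[perm], None, [grm.values[np.ix_(perm, perm)]])
        assert fit2.sigma2[0] == pytest.approx(fit.sigma2[0], rel=1e-5)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-5)

    def test_ai_and_em_reach_same_optimum(self):
        """AI with EM fallback and pure EM agree on 50 seeded instances."""
        agree = 0
        for seed in range(50):
            g, y = _sim_quantitative(100 + seed, n=60, m=80)
            grm = compute_grm(g)
            ai = fit_reml(y, None, [grm], tol=1e-9)
            em = fit_reml(y, None, [grm], method="em", tol=1e-10, max_iter=4000)
            agree += abs(ai.h2_obs_total - em.h2_obs_total) < 1e-4
        assert agree >= 48  # EM may hit max_iter on a flat likelihood

    def test_optimum_at_least_as_good_as_truth(self):
        g, y = _sim_quantitative(11, n=300, m=200, h2=0.4)
        grm = compute_grm(g)
        fit = fit_reml(y, None, [grm])
        at_truth = restricted_loglik(y, np.ones((300, 1)), [grm], [0.4], 0.6)
        assert fit.loglik >= at_truth - 1e-6

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_reml(np.zeros(10) + np.arange(10), None, [])
        g, y = _sim_quantitative(1, n=50, m=60)
        with pytest.raises(InvalidInputError):
            fit_reml(y[:-1], None, [compute_grm(g)])


class TestJointChromosomes:
    def test_causal_chromosome_captures_signal(self):
        """All causal SNPs on chr1 of 4: its component dominates (10 seeds)."""
        shares = []
        for seed in range(10):
            cfg = GenoSimConfig(
                n_snps=400, n_causal=60, h2_liab=0.5, prevalence_K=0.5,
                n_chromosomes=1, seed=300 + seed,
            )
            g = simulate_genotypes(cfg, n_samples=500)
            y = phenotype_frame(assign_liability_phenotypes(g, cfg))[
                "liability"
            ].to_numpy()
            # relabel chromosomes so every causal SNP sits on chr1 and the
            # remaining SNPs are spread over chrs 2-4
            from liabherit.simdata import _causal_model

            idx, _ = _causal_model(cfg, np.random.default_rng(cfg.seed + 1))
            rng = np.random.default_rng(seed)
            chroms = rng.integers(2, 5, size=400)
            chroms[idx] = 1
            g.snps["chrom"] = chroms
            jf = fit_joint_chromosomes(y, None, per_chromosome_grms(g))
            h2 = jf.joint.h2_obs
            labels = jf.joint.component_labels
            share = h2[labels.index("chr1")] / max(h2.sum(), 1e-12)
            shares.append(share)
        assert np.mean(shares) >= 0.8

    def test_permutation_of_grm_list_is_label_stable(self):
        cfg = GenoSimConfig(
            n_snps=200, n_causal=40, h2_liab=0.4, prevalence_K=0.5,
            n_chromosomes=4, seed=13,
        )
        g = simulate_genotypes(cfg, n_samples=300)
        y = phenotype_frame(assign_liability_phenotypes(g, cfg))["liability"].to_numpy()
        grms = per_chromosome_grms(g)
        a = fit_joint_chromosomes(y, None, grms)
        b = fit_joint_chromosomes(y, None, grms[::-1])
        da, db = a.per_chromosome_h2, b.per_chromosome_h2
        for k in da:
            assert db[k] == pytest.approx(da[k], abs=1e-4)

    def test_null_trait_components_near_zero(self):
        for seed in range(3):
            rng = np.random.default_rng(700 + seed)
            cfg = GenoSimConfig(
                n_snps=200, n_causal=0, h2_liab=0.0, prevalence_K=0.5,
                n_chromosomes=3, seed=seed,
            )
            g = simulate_genotypes(cfg, n_samples=300)
            y = rng.normal(size=300)
            jf = fit_joint_chromosomes(y, None, per_chromosome_grms(g))
            for h2, se_ in zip(jf.joint.h2_obs, jf.joint.h2_se):
                assert h2 < max(2 * se_, 0.02) + 1e-9


class TestPerSnpVariance:
    @staticmethod
    def _setup(seed, beta=0.0, n=400, m=200, snp_col=0):
        """Trait with an optional extra effect loaded on one genotyped SNP."""
        cfg = GenoSimConfig(
            n_snps=m, n_causal=30, h2_liab=0.3, prevalence_K=0.5,
            n_chromosomes=2, seed=seed,
        )
        g = simulate_genotypes(cfg, n_samples=n)
        y = phenotype_frame(assign_liability_phenotypes(g, cfg))["liability"].to_numpy()
        snp = g.dosages[:, snp_col].astype(float)
        if beta:
            z = (snp - snp.mean()) / snp.std()
            y = y + beta * z
        return g, y, snp

    def test_null_snp_attribution_near_zero(self):
        """An independent no-effect SNP changes the chromosome h2 by ~0."""
        rng = np.random.default_rng(99)
        diffs = []
        for seed in range(5):
            g, y, _ = self._setup(400 + seed)
            snp = rng.binomial(2, 0.3, size=y.size).astype(float)
            grms = per_chromosome_grms(g)
            diffs.append(per_snp_variance(y, None, grms, snp, "chr1"))
        assert abs(np.mean(diffs)) < 0.03

    def test_effect_snp_attribution_matches_single_locus_variance(self):
        """Attribution ~ beta^2/(1+beta^2), the SNP's variance fraction.

        The tested SNP is genotyped on chr1, so its effect is captured
        by the chr1 component and removed when it enters the design.
        """
        beta = 0.45
        expected = beta**2 / (1 + beta**2)
        diffs = []
        for seed in range(5):
            g, y, snp = self._setup(500 + seed, beta=beta, snp_col=0)
            assert g.snps["chrom"].iloc[0] == 1
            grms = per_chromosome_grms(g)
            diffs.append(per_snp_variance(y, None, grms, snp, "chr1"))
        mean_d = np.mean(diffs)
        assert abs(mean_d - expected) < 0.5 * expected + 0.05

    def test_duplicate_snp_column_dropped(self):
        g, y, snp = self._setup(600)
        grms = per_chromosome_grms(g)
        X = np.column_stack([np.ones(y.size), (snp - snp.mean()) / snp.std()])
        d = per_snp_variance(y, X, grms, snp, "chr1")
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_monomorphic_snp_rejected(self):
        g, y, _ = self._setup(601)
        grms = per_chromosome_grms(g)
        with pytest.raises(InvalidInputError):
            per_snp_variance(y, None, grms, np.full(y.size, 2.0), "chr1")


class TestStratifiedFit:
    @staticmethod
    def _case_control(seed, n=500):
        cfg = GenoSimConfig(
            n_snps=200, n_causal=40, h2_liab=0.5, prevalence_K=0.3, seed=seed
        )
        g = simulate_genotypes(cfg, n_samples=n)
        f = phenotype_frame(assign_liability_phenotypes(g, cfg))
        return g, f

    def test_single_subtype_equals_unstratified(self):
        g, f = self._case_control(21)
        y = f["status"].to_numpy()
        labels = np.where(y == 1, "only", None)
        grm = compute_grm(g)
        strat = stratified_fit(y, labels, "only", grm)
        full = fit_reml(y.astype(float), None, [grm])
        assert strat.h2_obs_total == pytest.approx(full.h2_obs_total, abs=1e-8)

    def test_equal_architecture_subtypes_agree(self):
        g, f = self._case_control(22, n=800)
        y = f["status"].to_numpy()
        labels = f["subtype"].to_numpy(dtype=object)
        grm = compute_grm(g)
        a = stratified_fit(y, labels, "subtype_a", grm)
        b = stratified_fit(y, labels, "subtype_b", grm)
        spread = abs(a.h2_obs_total - b.h2_obs_total)
        assert spread < 2 * (a.h2_total_se + b.h2_total_se)

    def test_empty_stratum_rejected(self):
        g, f = self._case_control(23)
        with pytest.raises(InvalidInputError):
            stratified_fit(
                f["status"].to_numpy(),
                f["subtype"].to_numpy(dtype=object),
                "no_such",
                compute_grm(g),
            )
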