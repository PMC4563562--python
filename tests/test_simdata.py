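"""Generators: determinism, Hardy-Weinberg sampling, liability structure."""

import numpy as np
import pytest

from liabherit import (
    GenoSimConfig,
    PedSimConfig,
    ascertain_case_control,
    assign_liability_phenotypes,
    phenotype_frame,
    simulate_genotypes,
    simulate_pedigree,
)
from liabherit.errors import InvalidConfigError, ResourceBudgetError


class TestSimulateGenotypes:
    def test_deterministic_under_fixed_seed(self, small_config):
        a = simulate_genotypes(small_config, n_samples=50)
        b = simulate_genotypes(small_config, n_samples=50)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.snps.equals(b.snps)

    def test_no_missing_when_rate_zero(self, small_config):
        g = simulate_genotypes(small_config, n_samples=50)
        assert not g.missing_mask().any()

    def test_missing_rate_respected(self, small_config):
        cfg = GenoSimConfig(
            **{**small_config.__dict__, "missing_rate": 0.1}
        )
        g = simulate_genotypes(cfg, n_samples=400)
        rate = g.missing_mask().mean()
        assert abs(rate - 0.1) < 0.01

    def test_sample_maf_matches_drawn_maf(self):
        """Sample MAF within 3 binomial SDs of its drawn value for >=95% of SNPs."""
        cfg = GenoSimConfig(
            n_snps=200, maf_low=0.2, maf_high=0.5, n_causal=0, prevalence_K=0.1, seed=4
        )
        n = 20_000
        g = simulate_genotypes(cfg, n_samples=n)
        drawn = g.snps["sim_maf"].to_numpy()
        observed = g.allele_freqs()
        sd = np.sqrt(drawn * (1 - drawn) / (2 * n))
        within = np.abs(observed - drawn) <= 3 * sd
        assert within.mean() >= 0.95

    def test_round_robin_chromosomes(self, small_config):
        g = simulate_genotypes(small_config, n_samples=10)
        counts = g.snps["chrom"].value_counts()
        assert len(counts) == small_config.n_chromosomes
        assert counts.max() - counts.min() <= 1

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            GenoSimConfig(n_snps=0)
        with pytest.raises(InvalidConfigError):
            GenoSimConfig(h2_liab=1.5)
        with pytest.raises(InvalidConfigError):
            GenoSimConfig(maf_low=0.4, maf_high=0.2)
        cfg = GenoSimConfig()
        with pytest.raises(InvalidConfigError):
            simulate_genotypes(cfg, n_samples=0)


class TestLiabilityPhenotypes:
    def test_pure_noise_case_fraction_matches_K(self):
        """With h2 = 0 the case fraction is binomial around K."""
        K = 0.2
        cfg = GenoSimConfig(n_snps=10, n_causal=0, h2_liab=0.0, prevalence_K=K, seed=9)
        g = simulate_genotypes(cfg, n_samples=100_000)
        f = phenotype_frame(assign_liability_phenotypes(g, cfg))
        se = np.sqrt(K * (1 - K) / len(f))
        assert abs(f["status"].mean() - K) < 3 * se

    def test_fully_heritable_status_determined_by_genes(self):
        cfg = GenoSimConfig(
            n_snps=100, n_causal=40, h2_liab=1.0, prevalence_K=0.3, seed=2
        )
        g = simulate_genotypes(cfg, n_samples=2000)
        f = phenotype_frame(assign_liability_phenotypes(g, cfg))
        np.testing.assert_allclose(f["liability"], f["genetic_value"], atol=1e-12)

    def test_variance_decomposition(self):
        """Regression of liability on genetic value: slope ~ 1, R^2 ~ h2."""
        cfg = GenoSimConfig(
            n_snps=200, n_causal=80, h2_liab=0.4, prevalence_K=0.1, seed=6
        )
        g = simulate_genotypes(cfg, n_samples=50_000)
        f = phenotype_frame(assign_liability_phenotypes(g, cfg))
        gv, li = f["genetic_value"].to_numpy(), f["liability"].to_numpy()
        slope = np.cov(li, gv)[0, 1] / np.var(gv)
        r2 = np.corrcoef(li, gv)[0, 1] ** 2
        assert abs(slope - 1.0) < 0.05
        assert abs(r2 - 0.4) < 0.02

    def test_subtype_labels_only_on_cases(self, small_config):
        g = simulate_genotypes(small_config, n_samples=500)
        f = phenotype_frame(assign_liability_phenotypes(g, small_config))
        assert f.loc[f.status == 0, "subtype"].isna().all()
        assert f.loc[f.status == 1, "subtype"].notna().all()


class TestAscertainment:
    def test_quotas_met_exactly(self):
        cfg = GenoSimConfig(
            n_snps=50, n_causal=10, h2_liab=0.5, prevalence_K=0.2,
            n_cases=80, n_controls=120, seed=3,
        )
        sample = ascertain_case_control(cfg)
        status = np.array([p.status for p in sample.phenotypes])
        assert status.sum() == 80
        assert (status == 0).sum() == 120
        assert sample.P == pytest.approx(0.4)
        assert sample.K == 0.2

    def test_controls_only(self):
        cfg = GenoSimConfig(
            n_snps=20, n_causal=0, prevalence_K=0.3, n_cases=0, n_controls=50, seed=1
        )
        sample = ascertain_case_control(cfg)
        assert sample.P == 0.0
        assert all(p.status == 0 for p in sample.phenotypes)

    def test_case_rate_near_half_at_K_half(self):
        """K=0.5 with h2=0: population draws are cases ~half the time."""
        cfg = GenoSimConfig(
            n_snps=10, n_causal=0, h2_liab=0.0, prevalence_K=0.5,
            n_cases=2000, n_controls=2000, seed=8,
        )
        g = simulate_genotypes(cfg, n_samples=20_000)
        f = phenotype_frame(assign_liability_phenotypes(g, cfg))
        assert abs(f["status"].mean() - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_truncation_raises_case_genetic_mean(self):
        """Cases have higher mean genetic value than controls, every seed."""
        for seed in range(10):
            cfg = GenoSimConfig(
                n_snps=100, n_causal=40, h2_liab=0.5, prevalence_K=0.1,
                n_cases=500, n_controls=500, seed=seed,
            )
            sample = ascertain_case_control(cfg)
            gv = np.array([p.genetic_value for p in sample.phenotypes])
            status = np.array([p.status for p in sample.phenotypes])
            assert gv[status == 1].mean() > gv[status == 0].mean()

    def test_budget_error_for_tiny_K(self):
        cfg = GenoSimConfig(
            n_snps=10, n_causal=5, prevalence_K=0.0001, n_cases=500, n_controls=10,
            max_draws=10_000, seed=0,
        )
        with pytest.raises(ResourceBudgetError):
            ascertain_case_control(cfg)

    def test_deterministic(self):
        cfg = GenoSimConfig(
            n_snps=30, n_causal=5, prevalence_K=0.2, n_cases=30, n_controls=30, seed=5
        )
        a = ascertain_case_control(cfg)
        b = ascertain_case_control(cfg)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert [p.liability for p in a.phenotypes] == [p.liability for p in b.phenotypes]


class TestSimulatePedigree:
    @staticmethod
    def _sib_pairs(ped, values):
        key = ped.table["father"] + "|" + ped.table["mother"]
        known = (ped.table["father"] != "0") & (ped.table["mother"] != "0")
        pairs = []
        for _, grp in ped.table[known].groupby(key[known]):
            idx = grp.index.to_numpy()
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    pairs.append((values[idx[i]], values[idx[j]]))
        return np.asarray(pairs)

    def test_sib_liability_correlation_half_h2(self):
        cfg = PedSimConfig(
            n_families=25_000, n_generations=2, sibship_mean=3.0,
            h2_liab=0.5, prevalence_K=0.1, seed=12,
        )
        ped, phenos, _ = simulate_pedigree(cfg)
        liab = np.array([p.liability for p in phenos])
        pairs = self._sib_pairs(ped, liab)
        assert len(pairs) >= 50_000
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r - 0.25) < 0.01

    def test_zero_heritability_sibs_uncorrelated(self):
        cfg = PedSimConfig(
            n_families=25_000, n_generations=2, sibship_mean=3.0,
            h2_liab=0.0, prevalence_K=0.1, seed=13,
        )
        ped, phenos, _ = simulate_pedigree(cfg)
        liab = np.array([p.liability for p in phenos])
        pairs = self._sib_pairs(ped, liab)
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r) < 0.02

    def test_founder_genetic_variance_near_h2(self):
        cfg = PedSimConfig(
            n_families=5000, n_generations=2, sibship_mean=2.0,
            h2_liab=0.6, prevalence_K=0.1, seed=14,
        )
        ped, phenos, _ = simulate_pedigree(cfg)
        founders = ped.is_founder()
        a = np.array([p.genetic_value for p in phenos])[founders]
        assert abs(a.var() - 0.6) < 0.03

    def test_two_generation_family_topology(self):
        cfg = PedSimConfig(n_families=1, n_generations=2, sibship_mean=2.0, seed=3)
        ped, _, _ = simulate_pedigree(cfg)
        order = ped.topological_order()
        pos = {i: k for k, i in enumerate(order)}
        parents = ped.parent_indices()
        for i in range(len(ped)):
            for p in parents[i]:
                if p >= 0:
                    assert pos[p] < pos[i]

    def test_covariate_effects_enter_liability(self):
        cfg = PedSimConfig(
            n_families=4000, n_generations=2, sibship_mean=2.0, h2_liab=0.3,
            prevalence_K=0.2, covariate_effects=[("exposure", 0.5)], seed=15,
        )
        _, phenos, covs = simulate_pedigree(cfg)
        liab = np.array([p.liability for p in phenos])
        x = covs["exposure"].to_numpy()
        slope = np.cov(liab, x)[0, 1] / np.var(x)
        assert abs(slope - 0.5) < 0.05

    def test_deterministic(self):
        cfg = PedSimConfig(n_families=20, n_generations=3, seed=21)
        a = simulate_pedigree(cfg)
        b = simulate_pedigree(cfg)
        assert a[0].table.equals(b[0].table)
        assert [p.liability for p in a[1]] == [p.liability for p in b[1]]

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            PedSimConfig(n_generations=1)
        with pytest.raises(InvalidConfigError):
            PedSimConfig(sibship_mean=0.5)
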