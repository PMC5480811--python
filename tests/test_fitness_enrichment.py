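import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selpleio.fitness_enrichment import (adjust_lrs, compute_grm,
                                         gene_based_test, gene_perm_p,
                                         gene_set_enrichment, lmm_assoc,
                                         multiple_testing, permute_snp_p,
                                         set_enrichment_test)
from selpleio.lmm import KernelLmm
from selpleio.synthetic_data import (EffectSpec, simulate_fitness,
                                     simulate_unlinked_panel)


def pheno_table(n, rng, lrs=None):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": 1, "birth_year": rng.integers(1900, 1960, n),
        "lrs_raw": rng.poisson(2.5, n) if lrs is None else lrs,
        "education": rng.integers(0, 2, n), "smoking": rng.integers(0, 2, n),
        "born_in_country": rng.integers(0, 2, n),
        "estrogen_use": rng.integers(0, 2, n)})


class TestAdjustLrs:
    def test_division_by_group_mean(self, rng):
        df = pheno_table(300, rng)
        adj = adjust_lrs(df, n_groups=6)
        g = adj.loc[0, "birth_group"]
        mean = adj.loc[adj["birth_group"] == g, "lrs_raw"].mean()
        assert adj.loc[0, "lrs_adjusted"] == pytest.approx(
            adj.loc[0, "lrs_raw"] / mean)

    def test_three_children_group_mean_two(self, rng):
        """A woman with 3 children in a group with mean 2.0 scores 1.5."""
        df = pheno_table(12, rng, lrs=[3, 1, 2, 2, 2, 2, 3, 1, 2, 2, 2, 2])
        df["birth_year"] = np.repeat([1900, 1930], 6)
        adj = adjust_lrs(df, n_groups=2)
        assert adj.loc[0, "lrs_adjusted"] == pytest.approx(1.5)

    def test_every_group_mean_exactly_one(self, rng):
        adj = adjust_lrs(pheno_table(600, rng), n_groups=6)
        means = adj.groupby("birth_group")["lrs_adjusted"].mean()
        np.testing.assert_allclose(means, 1.0, atol=1e-12)
        assert adj["birth_group"].value_counts().nunique() == 1  # equal count

    def test_constant_lrs_all_ones(self, rng):
        adj = adjust_lrs(pheno_table(60, rng, lrs=np.full(60, 2)), n_groups=6)
        np.testing.assert_allclose(adj["lrs_adjusted"], 1.0)

    def test_zero_mean_group_raises(self, rng):
        df = pheno_table(12, rng, lrs=np.zeros(12, dtype=int))
        with pytest.raises(ValueError, match="zero mean"):
            adjust_lrs(df, n_groups=2)


class TestGrm:
    def test_duplicate_individuals_share_kernel_entry(self):
        panel = simulate_unlinked_panel(30, 400, seed=1)
        hap = panel.hap_matrix.copy()
        hap[2:4] = hap[0:2]  # sample 1 duplicates sample 0
        import dataclasses
        panel = dataclasses.replace(panel, hap_matrix=hap)
        grm = compute_grm(panel, prune_r2=1.1)
        assert grm.kernel[0, 1] == pytest.approx(grm.kernel[0, 0])

    def test_unrelated_offdiagonal_near_zero(self):
        panel = simulate_unlinked_panel(40, 900, seed=2)
        grm = compute_grm(panel, prune_r2=1.1)
        m = len(grm.source_snp_ids)
        off = grm.kernel[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 3 / np.sqrt(m)
        assert np.mean(np.diag(grm.kernel)) == pytest.approx(1.0, abs=0.1)

    def test_exclusion_zone_respected(self):
        panel = simulate_unlinked_panel(30, 300, seed=3)
        lo, hi = 200_000, 400_000
        grm = compute_grm(panel, prune_r2=1.1,
                          exclude_intervals=[(lo, hi)], excl_window_bp=50_000)
        pos = {str(s): p for s, p in zip(panel.snp_ids, panel.positions_bp)}
        for sid in grm.source_snp_ids:
            assert not (lo - 50_000 <= pos[str(sid)] <= hi + 50_000)

    def test_pruning_limits_pairwise_r2(self):
        panel = simulate_unlinked_panel(60, 200, seed=4)
        # duplicate neighboring columns to create perfect LD
        hap = panel.hap_matrix.copy()
        hap[:, 1::2] = hap[:, 0::2]
        import dataclasses
        panel = dataclasses.replace(panel, hap_matrix=hap)
        grm = compute_grm(panel, prune_r2=0.2, min_snps=10)
        from selpleio.locus_mapping import ld_r2
        idx = [panel.snp_index(str(s)) for s in grm.source_snp_ids]
        for a, b in zip(idx[:-1], idx[1:]):
            if panel.positions_bp[b] - panel.positions_bp[a] <= 500_000:
                assert ld_r2(panel.hap_matrix[:, a],
                             panel.hap_matrix[:, b]) <= 0.2 + 1e-12

    def test_too_few_snps_raises(self):
        panel = simulate_unlinked_panel(20, 60, seed=5)
        with pytest.raises(ValueError, match="kernel"):
            compute_grm(panel, prune_r2=1.1, min_snps=100)


class TestKernelLmm:
    def dense_gls_oracle(self, y, X, K, sigma_g2, sigma_e2):
        V = sigma_g2 * K + sigma_e2 * np.eye(len(y))
        Vi = np.linalg.inv(V)
        return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)

    def test_matches_dense_gls_at_fixed_delta(self, rng):
        n = 80
        panel = simulate_unlinked_panel(n, 500, seed=6)
        K = compute_grm(panel, prune_r2=1.1).kernel
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        model = KernelLmm(K)
        for delta in (0.5, 2.0):
            fit = model.fit(y, X, delta=delta)
            oracle = self.dense_gls_oracle(y, X, K, 1.0, delta)
            np.testing.assert_allclose(fit.beta, oracle, atol=1e-6)

    def test_reml_profile_no_worse_than_grid(self, rng):
        n = 60
        panel = simulate_unlinked_panel(n, 400, seed=7)
        K = compute_grm(panel, prune_r2=1.1).kernel
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        model = KernelLmm(K)
        best = model.fit(y, X)
        for d in 10.0 ** np.linspace(-3, 3, 13):
            other = model.fit(y, X, delta=d)
            assert best.reml_loglik >= other.reml_loglik - 1e-6

    def test_scan_matches_individual_fits(self, rng):
        n = 50
        panel = simulate_unlinked_panel(n, 300, seed=8)
        K = compute_grm(panel, prune_r2=1.1).kernel
        W = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        snps = rng.normal(size=(n, 5))
        model = KernelLmm(K)
        delta = model.fit(y, W).delta
        beta, se, p = model.scan(y, W, snps, delta)
        for j in range(5):
            single = model.fit(y, np.column_stack([W, snps[:, j]]),
                               delta=delta)
            assert beta[j] == pytest.approx(single.beta[-1], rel=1e-6)

    def test_non_psd_kernel_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            KernelLmm(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLmmAssoc:
    def test_no_genetic_variance_matches_ols(self, rng):
        """With the kernel ignored in truth, beta matches plain OLS."""
        n = 120
        panel = simulate_unlinked_panel(n, 300, seed=9)
        dosage = panel.dosage().astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.3 * dosage[:, 0] + cov @ [0.5, -0.2] + rng.normal(0, 1, n)
        grm = compute_grm(panel, prune_r2=1.1)
        out = lmm_assoc(y, cov, grm, dosage[:, :3], snp_ids=panel.snp_ids[:3])
        X = np.column_stack([np.ones(n), cov, dosage[:, 0]])
        ols = np.linalg.lstsq(X, y, rcond=None)[0][-1]
        assert out.loc[0, "beta"] == pytest.approx(ols, abs=0.02)

    def test_planted_beta_recovered(self):
        hits = 0
        n_rep = 12
        for k in range(n_rep):
            panel = simulate_unlinked_panel(400, 300, seed=100 + k)
            snp = str(panel.snp_ids[0])
            spec = EffectSpec(lrs_snp_betas={snp: 0.2}, lrs_residual_sd=0.6,
                              lrs_h2=0.2)
            pheno = simulate_fitness(panel, spec, seed=k)
            adj = adjust_lrs(pheno)
            grm = compute_grm(panel, prune_r2=1.1)
            cov = adj[["education", "smoking", "born_in_country",
                       "estrogen_use"]].to_numpy(float)
            out = lmm_assoc(adj["lrs_adjusted"].to_numpy(), cov, grm,
                            panel.dosage()[:, :1].astype(float))
            expected = 0.2 / pheno["lrs_raw"].mean()  # adjusted scale
            hits += abs(out.loc[0, "beta"] - expected) <= 2 * out.loc[0, "se"]
        assert hits >= 0.75 * n_rep

    def test_singular_covariates_error(self, rng):
        n = 50
        panel = simulate_unlinked_panel(n, 300, seed=10)
        grm = compute_grm(panel, prune_r2=1.1)
        cov = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="singular"):
            lmm_assoc(rng.normal(size=n), cov, grm,
                      panel.dosage()[:, :1].astype(float))


class TestPermuteSnpP:
    def test_floor(self, rng):
        pool_p = rng.uniform(size=2000)
        pool_maf = rng.uniform(0.0, 0.5, 2000)
        p = permute_snp_p(np.array([1e-12]), np.array([0.25]), pool_p,
                          pool_maf, n_perm=10_000, seed=1)
        assert p == pytest.approx(1 / 10_001)

    def test_median_target(self, rng):
        pool_p = rng.uniform(size=5000)
        pool_maf = np.full(5000, 0.25)
        med = np.median(pool_p)
        p = permute_snp_p(np.array([med]), np.array([0.25]), pool_p,
                          pool_maf, n_perm=10_000, seed=2)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_null_uniform(self, rng):
        pool_p = rng.uniform(size=3000)
        pool_maf = rng.uniform(0.0, 0.5, 3000)
        targets = rng.uniform(size=400)
        tmaf = rng.uniform(0.0, 0.5, 400)
        ps = permute_snp_p(targets, tmaf, pool_p, pool_maf, n_perm=1000,
                           seed=3)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_bin_widened(self, rng):
        pool_p = rng.uniform(size=150)
        pool_maf = np.full(150, 0.05)  # all pool in one low bin
        p = permute_snp_p(np.array([0.5]), np.array([0.45]), pool_p,
                          pool_maf, n_perm=100, seed=4, min_bin_size=50)
        assert np.isfinite(p)


class TestSetEnrichment:
    def test_draws_match_maf_histogram(self, rng):
        pool_p = rng.uniform(size=3000)
        pool_maf = rng.uniform(0, 0.5, 3000)
        tgt_maf = rng.uniform(0, 0.5, 150)
        res = set_enrichment_test(rng.uniform(size=150), tgt_maf, pool_p,
                                  pool_maf, n_draws=20, seed=5)
        assert res.n_target == 150
        assert len(res.draw_sig_counts) == 20

    def test_planted_effects_hit_floor(self, rng):
        target_p = np.full(100, 1e-4)  # strongly enriched set
        res = set_enrichment_test(target_p, rng.uniform(0, 0.5, 100),
                                  rng.uniform(size=3000),
                                  rng.uniform(0, 0.5, 3000),
                                  n_draws=100, seed=6)
        assert res.perm_p_set == pytest.approx(1 / 101)
        assert res.ks_one_sided_p < 1e-6

    def test_null_set_not_significant(self, rng):
        ps = []
        for k in range(20):
            r = np.random.default_rng(k)
            pool_p = r.uniform(size=2000)
            pool_maf = r.uniform(0, 0.5, 2000)
            pick = r.choice(2000, 100, replace=False)
            res = set_enrichment_test(pool_p[pick], pool_maf[pick],
                                      np.delete(pool_p, pick),
                                      np.delete(pool_maf, pick),
                                      n_draws=50, seed=k)
            ps.append(res.perm_p_set)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.25


class TestGeneBasedTest:
    def test_single_snp_reduces_to_chi2_tail(self):
        """One SNP with z^2 = 4: T = 4, lambda = {1}, p = 0.0455."""
        gt = gene_based_test(np.array([2.0]), np.array([[1.0]]))
        assert gt.T == pytest.approx(4.0)
        assert gt.p_gene == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-3)
        assert gt.p_gene == pytest.approx(0.0455, abs=5e-4)

    def test_two_perfectly_correlated_snps(self):
        """Two r = 1 SNPs each z^2 = 4: T = 8, lambda = {2, 0}, same p."""
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        gt = gene_based_test(np.array([2.0, 2.0]), corr)
        assert gt.T == pytest.approx(8.0)
        np.testing.assert_allclose(sorted(gt.eigenvalues), [0.0, 2.0],
                                   atol=1e-12)
        assert gt.p_gene == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-2)

    def test_independent_snps_match_chi2_m(self):
        """Identity correlation: p equals the exact chi^2_m tail."""
        for m in (2, 3, 5):
            z = np.full(m, 1.3)
            gt = gene_based_test(z, np.eye(m))
            exact = stats.chi2.sf(np.sum(z ** 2), m)
            assert gt.p_gene == pytest.approx(exact, rel=1e-3)

    def test_eigenvalue_sum_equals_snp_count(self, rng):
        x = rng.normal(size=(50, 8))
        corr = np.corrcoef(x, rowvar=False)
        gt = gene_based_test(rng.normal(size=8), corr)
        assert np.sum(gt.eigenvalues) == pytest.approx(8.0, abs=1e-8)

    def test_small_p_refined_by_monte_carlo(self, rng):
        x = rng.normal(size=(60, 6))
        corr = np.corrcoef(x, rowvar=False)
        z = np.full(6, 4.0)
        gt = gene_based_test(z, corr, seed=1)
        assert gt.method == "monte_carlo"
        # Satterthwaite and MC must agree to within MC error
        lam = gt.eigenvalues
        c = np.sum(lam ** 2) / np.sum(lam)
        d = np.sum(lam) ** 2 / np.sum(lam ** 2)
        satt = stats.chi2.sf(gt.T / c, d)
        assert gt.p_gene == pytest.approx(satt, rel=1.0, abs=5e-4)


class TestGenePermAndSet:
    def test_gene_floor(self, rng):
        assert gene_perm_p(1e-9, rng.uniform(0.1, 1, 100)) == pytest.approx(1 / 101)

    def test_gene_null_uniformish(self, rng):
        ps = [gene_perm_p(rng.uniform(), rng.uniform(size=100))
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_set_enrichment_floor_with_planted_genes(self, rng):
        target = np.full(76, 1e-3)
        draws = rng.uniform(size=(300, 76))
        assert gene_set_enrichment(target, draws) == pytest.approx(1 / 301)


class TestMultipleTesting:
    def test_bonferroni_at_panel_threshold(self):
        """p = 0.05/76 with 76 tests Bonferroni-adjusts to exactly 0.05."""
        p = np.full(76, 1.0)
        p[0] = 0.05 / 76
        bonf, _ = multiple_testing(p)
        assert bonf[0] == pytest.approx(0.05)
        assert 0.05 / 76 == pytest.approx(0.000657, abs=1e-6)

    def test_bh_step_up_by_hand(self):
        """p = {0.01, 0.02, 0.03} with m = 3: q = {0.03, 0.03, 0.03}."""
        _, fdr = multiple_testing(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(fdr, [0.03, 0.03, 0.03], atol=1e-12)

    def test_all_ones_stay_ones(self):
        bonf, fdr = multiple_testing(np.ones(5))
        np.testing.assert_allclose(bonf, 1.0)
        np.testing.assert_allclose(fdr, 1.0)
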