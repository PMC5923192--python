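"""Mixed-model GWAS: GRM, REML, GLS scan and their oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from pedigrec.gwas import (RecombinationGwas, _rotated_reml_loglik,
                           compute_grm, fit_null_reml, pedigree_a_matrix,
                           reml_loglik_dense, snp_scan)


def sim_panel(rng, n, m):
    p = rng.uniform(0.1, 0.9, m)
    return rng.binomial(2, p, size=(n, m)).astype(float)


class TestGrm:
    def test_single_snp_half_frequency(self):
        K = compute_grm(np.array([[0.0], [2.0]]), freqs=np.array([0.5]))
        np.testing.assert_allclose(K, [[2, -2], [-2, 2]])

    def test_duplicated_animal_rows(self):
        rng = np.random.default_rng(0)
        G = sim_panel(rng, 5, 50)
        G[1] = G[0]
        K = compute_grm(G)
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        G = sim_panel(rng, 50, 500)
        K = compute_grm(G)
        p = G.mean(0) / 2
        denom = 2 * np.sum(p * (1 - p))
        naive = np.empty((50, 50))
        for i in range(50):
            for j in range(50):
                naive[i, j] = np.sum((G[i] - 2 * p) * (G[j] - 2 * p)) / denom
        np.testing.assert_allclose(K, naive, atol=1e-10)

    def test_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(2)
        K = compute_grm(sim_panel(rng, 200, 2000))
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.1)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            compute_grm(np.full((4, 3), 2.0))   # fixed allele everywhere

    def test_missing_genotypes_mean_imputed(self):
        rng = np.random.default_rng(3)
        G = sim_panel(rng, 30, 100)
        Gm = G.copy()
        Gm[rng.random(G.shape) < 0.05] = -1
        K = compute_grm(Gm)
        assert np.isfinite(K).all()
        np.testing.assert_allclose(K, K.T, atol=1e-12)


class TestPedigreeKinship:
    def test_parent_offspring_half(self):
        ped = pd.DataFrame({"sire": ["0", "0", "a"], "dam": ["0", "0", "b"]},
                           index=["a", "b", "c"])
        A = pedigree_a_matrix(ped, ["a", "b", "c"])
        assert A[0, 2] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)        # unrelated parents

    def test_fullsib_and_inbred(self):
        ped = pd.DataFrame(
            {"sire": ["0", "0", "a", "a", "c"], "dam": ["0", "0", "b", "b", "d"]},
            index=["a", "b", "c", "d", "e"])
        A = pedigree_a_matrix(ped, ["c", "d", "e"])
        assert A[0, 1] == pytest.approx(0.5)        # full sibs
        assert A[2, 2] == pytest.approx(1.25)       # full-sib mating


class TestReml:
    def test_rotated_equals_dense_loglik(self):
        rng = np.random.default_rng(4)
        n = 40
        K = compute_grm(sim_panel(rng, n, 200))
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0, None)
        for sa, se in ((1.0, 1.0), (0.3, 2.0), (5.0, 0.1)):
            dense = reml_loglik_dense(y, X, K, sa, se)
            rot = _rotated_reml_loglik(U.T @ y, U.T @ X, s, sa, se)
            assert rot == pytest.approx(dense, abs=1e-8)

    def test_heritability_recovery(self):
        rng = np.random.default_rng(5)
        n = 500
        K = compute_grm(sim_panel(rng, n, 1000))
        s, U = np.linalg.eigh(K)
        u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=n))
        y = u + rng.normal(size=n)
        fit = fit_null_reml(y, K)
        assert abs(fit.heritability - 0.5) < 0.1

    def test_null_heritability_small(self):
        rng = np.random.default_rng(6)
        n = 500
        K = compute_grm(sim_panel(rng, n, 1000))
        h2 = [fit_null_reml(rng.normal(size=n), K).heritability
              for _ in range(20)]
        assert np.median(h2) < 0.15

    def test_identity_kinship_flagged_and_reduces_to_ols(self):
        rng = np.random.default_rng(7)
        n, m = 80, 40
        y = rng.normal(size=n)
        fit = fit_null_reml(y, np.eye(n))
        assert fit.flag == "indeterminate"
        assert fit.sigma_a2 == 0.0
        G = sim_panel(rng, n, m)
        scan = snp_scan(y, G, null=fit)
        # dense ordinary-regression oracle per SNP
        for j in range(m):
            X = np.column_stack([np.ones(n), G[:, j]])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            cov = np.linalg.inv(X.T @ X) * fit.sigma_e2
            z2 = beta[1] ** 2 / cov[1, 1]
            assert scan.loc[j, "beta"] == pytest.approx(beta[1], abs=1e-8)
            assert scan.loc[j, "p"] == pytest.approx(chi2.sf(z2, 1), abs=1e-8)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            fit_null_reml(np.array([np.nan, 1.0, 2.0]), np.eye(3))


class TestScan:
    def test_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        n, m = 120, 60
        G = sim_panel(rng, n, m)
        K = compute_grm(G)
        y = rng.normal(size=n)
        p1 = snp_scan(y, G, K=K)["p"]
        p2 = snp_scan(3.0 * y + 7.0, G, K=K)["p"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_monomorphic_snp_skipped(self):
        rng = np.random.default_rng(9)
        n = 50
        G = sim_panel(rng, n, 10)
        G[:, 4] = 1.0
        out = snp_scan(rng.normal(size=n), G, K=np.eye(n))
        assert not out.loc[4, "tested"]
        assert np.isnan(out.loc[4, "p"])
        assert out.attrs["n_tests"] == 9

    def test_null_type_i_calibration(self):
        """200 animals x 2000 SNPs, polygenic background on K, no SNP
        effects: fraction of p < 0.05 within 3 binomial SEs of 0.05."""
        rng = np.random.default_rng(10)
        n, m = 200, 2000
        G = sim_panel(rng, n, m)
        K = compute_grm(G)
        s, U = np.linalg.eigh(K)
        u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=n))
        # polygenic background drawn on K, independent of any single SNP
        y = 0.7 * u + rng.normal(size=n)
        out = snp_scan(y, G, K=K)
        frac = (out["p"] < 0.05).mean()
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / m)

    def test_causal_snp_recovered(self):
        """A SNP explaining (0.5 sd)^2 of the phenotype is the top hit
        with an unbiased effect estimate in most replicates."""
        hits = 0
        betas, ses = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, m = 400, 300
            G = sim_panel(rng, n, m)
            K = compute_grm(G)
            g = G[:, 17]
            gs = (g - g.mean()) / g.std()
            s, U = np.linalg.eigh(K)
            u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=n))
            noise = 0.5 * u + np.sqrt(1 - 0.25) * rng.normal(size=n)
            beta_true = 0.5 * np.std(noise) / g.std() * g.std()  # 0.5 sd units
            y = 0.5 * np.std(noise) / g.std() * g + noise
            out = snp_scan(y, G, K=K)
            if out["p"].idxmin() == 17:
                hits += 1
            betas.append(out.loc[17, "beta"])
            ses.append(out.loc[17, "se"])
        assert hits >= 8
        # mean estimate within 3 combined SEs of the mean true effect
        assert abs(np.mean(betas) - np.mean(beta_true)) < 3 * np.mean(ses)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, clean_sim, clean_records):
        from pedigrec.phenotypes import adjusted_recombination_rate
        male = [r for r in clean_records if r.sex == "M"]
        ph = adjusted_recombination_rate(male)
        model = RecombinationGwas(ph[["animal", "phenotype"]],
                                  clean_sim.cohort)
        res = model.fit()
        assert len(res.table) == clean_sim.cohort.markers.n_snps
        text = res.summary()
        assert "sigma_a^2" in text and "Bonferroni" in text
        assert res.table["p"].dropna().between(0, 1).all()

    def test_pedigree_kinship_option(self, clean_sim, clean_records):
        from pedigrec.phenotypes import adjusted_recombination_rate
        male = [r for r in clean_records if r.sex == "M"][:40]
        ph = adjusted_recombination_rate(male)
        model = RecombinationGwas(ph[["animal", "phenotype"]],
                                  clean_sim.cohort, kinship="pedigree")
        assert model.K.shape[0] == len(model.animals)
        assert np.allclose(model.K, model.K.T)
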