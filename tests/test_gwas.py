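"""Relationship matrices, REML null model, GLS scans and eGWAS labelling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fenet.gwas import (
    Grm,
    VarianceComponents,
    assoc_scan,
    bh_qvalues,
    compute_grm,
    design_matrix,
    egwas_scan,
    fit_null_model,
)
from fenet.simdata import ExpressionMatrix
from tests.conftest import make_genotypes


class TestGrm:
    def test_hand_evaluated_entry(self):
        # one SNP, p = 0.5, individuals coded [2, 2, 0, 0]:
        # G_12 = (2-1)(2-1) / (2*0.5*0.5) = 2.0
        G = make_genotypes(np.array([[2], [2], [0], [0]]))
        K = compute_grm(G, method="per-snp-standardized")
        assert K.matrix[0, 1] == pytest.approx(2.0)

    def test_heterozygote_diagonal_zero(self):
        # all-het individual at p = 0.5 contributes (1-1)^2 = 0 per SNP
        G = make_genotypes(np.array([[1, 1], [1, 1], [2, 2], [0, 0]]))
        K = compute_grm(G)
        assert K.matrix[0, 0] == pytest.approx(0.0)

    def test_monomorphic_subset_rejected(self):
        G = make_genotypes(np.array([[2, 1], [2, 0], [2, 1]]))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(G)

    def test_methods_agree_on_uniform_maf(self, qc_genotypes_small):
        a = compute_grm(qc_genotypes_small, method="per-snp-standardized").matrix
        b = compute_grm(qc_genotypes_small, method="overall-scaled").matrix
        tri = np.triu_indices_from(a, 1)
        assert np.corrcoef(a[tri], b[tri])[0, 1] > 0.99

    def test_diagonal_near_one(self, qc_genotypes_small):
        K = compute_grm(qc_genotypes_small)
        assert abs(np.diag(K.matrix).mean() - 1.0) < 0.1


class TestNullModel:
    def test_identity_K_flagged_nonidentifiable(self):
        rng = np.random.default_rng(0)
        n = 60
        K = Grm(np.eye(n), [f"i{j}" for j in range(n)], "per-snp-standardized", 100)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        with pytest.warns(UserWarning, match="identifiable"):
            vc = fit_null_model(rng.normal(size=n), X, K)
        assert not vc.identifiable

    def test_null_heritability_near_zero(self, qc_genotypes_small):
        K = compute_grm(qc_genotypes_small)
        n = K.matrix.shape[0]
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(n), rng.uniform(121, 148, n)])
        h2s = [fit_null_model(rng.standard_normal(n), X, K).h2 for _ in range(20)]
        assert np.mean(np.array(h2s) <= 0.10) >= 0.8

    def test_h2_recovery_study_scale(self):
        """REML recovers h2 = 0.5 on a 350-animal half-sib GRM design."""
        from fenet.pheno import qc_genotypes
        from fenet.simdata import SimConfig, simulate_population

        cfg = SimConfig(n_individuals=350, n_families=5, n_snps=1200,
                        n_chromosomes=10, seed=21)
        G, _ = qc_genotypes(simulate_population(cfg).genotypes)
        K = compute_grm(G)
        d, U = np.linalg.eigh(K.matrix)
        L = U * np.sqrt(np.clip(d, 0, None))
        n = len(d)
        h2s = []
        for s in range(15):
            rng = np.random.default_rng(50 + s)
            g = L @ rng.standard_normal(n) * np.sqrt(0.5)
            X = np.column_stack([np.ones(n), rng.uniform(121, 148, n)])
            y = X @ np.array([1.0, 0.01]) + g + rng.standard_normal(n) * np.sqrt(0.5)
            h2s.append(fit_null_model(y, X, K).h2)
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.1)


def _ols_oracle(y, X, s):
    """Per-SNP ordinary least squares with normal-approximation p-values."""
    Xf = np.column_stack([X, s])
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    r = y - Xf @ beta
    df = len(y) - Xf.shape[1]
    s2 = r @ r / df
    cov = s2 * np.linalg.inv(Xf.T @ Xf)
    b, se = beta[-1], np.sqrt(cov[-1, -1])
    z = b / se
    return b, se, 2 * stats.norm.sf(abs(z))


class TestScan:
    def test_sigma_u_zero_equals_ols(self):
        rng = np.random.default_rng(5)
        n, m = 60, 40
        codes = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        G = make_genotypes(codes)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        K = Grm(np.eye(n), G.ids, "per-snp-standardized", m)
        vc = VarianceComponents(0.0, 1.0, False, False,
                                eigvals=np.ones(n), eigvecs=np.eye(n))
        res = assoc_scan(y, X, K, G, vc)
        for k in range(0, m, 7):
            b, se, p = _ols_oracle(y, X, codes[:, k].astype(float))
            assert res["effect"].iloc[k] == pytest.approx(b, abs=1e-8)
            assert res["se"].iloc[k] == pytest.approx(se, abs=1e-8)
            assert res["p"].iloc[k] == pytest.approx(p, abs=1e-8)

    def test_allele_swap_flips_sign_only(self):
        rng = np.random.default_rng(8)
        n, m = 80, 15
        codes = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        G = make_genotypes(codes)
        G_sw = make_genotypes(2 - codes)
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        K = Grm(np.eye(n), G.ids, "per-snp-standardized", m)
        vc = VarianceComponents(0.0, 1.0, False, False,
                                eigvals=np.ones(n), eigvecs=np.eye(n))
        a = assoc_scan(y, X, K, G, vc)
        b = assoc_scan(y, X, K, G_sw, vc)
        assert np.allclose(a["z"], -b["z"], atol=1e-10)
        assert np.allclose(a["p"], b["p"], atol=1e-12)

    def test_planted_qtl_detected_with_correct_sign(self, qc_genotypes_small):
        G = qc_genotypes_small
        K = compute_grm(G)
        n = G.n_individuals
        pvals, signs = [], []
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            k = rng.integers(0, G.n_snps)
            snp = G.codes[:, k].astype(float)
            if snp.std() == 0:
                continue
            beta = 0.8 / snp.std()       # QTL explaining a large variance share
            y = beta * snp + rng.standard_normal(n)
            X = np.ones((n, 1))
            vc = fit_null_model(y, X, K)
            res = assoc_scan(y, X, K, G, vc)
            pvals.append(res["p"].iloc[k])
            signs.append(np.sign(res["effect"].iloc[k]))
        assert np.median(pvals) < 1e-3
        assert np.mean(np.array(signs) > 0) >= 0.9

    def test_permutation_null_calibrated(self, qc_genotypes_small):
        G = qc_genotypes_small
        K = compute_grm(G)
        n = G.n_individuals
        X = np.ones((n, 1))
        rates = []
        for s in range(10):
            rng = np.random.default_rng(400 + s)
            y = rng.standard_normal(n)       # exchangeable: permuted phenotype
            vc = VarianceComponents(0.0, 1.0, False, False,
                                    eigvals=np.ones(n), eigvecs=np.eye(n))
            Ki = Grm(np.eye(n), list(G.ids), "per-snp-standardized", G.n_snps)
            res = assoc_scan(y, X, Ki, G, vc)
            rates.append((res["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.015)


class TestBH:
    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=57)
        q = bh_qvalues(p)
        m = len(p)
        # naive: q_i = min over j with p_j >= p_i of m*p_j/rank_j
        order = np.argsort(p)
        naive = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            naive[i] = min(running, 1.0)
        assert np.allclose(q, naive, atol=1e-12)
        # rank-1 q-value is at most m * p_min (monotonization can only lower it)
        assert q[np.argmin(p)] <= min(1.0, m * p.min()) + 1e-12


def _tiny_expression(n=30):
    rng = np.random.default_rng(9)
    codes = rng.binomial(2, 0.4, size=(n, 6)).astype(np.int8)
    positions = [100_000, 900_000, 1_500_000, 2_500_000, 3_000_000, 3_500_000]
    G = make_genotypes(codes, chrom="1", positions=positions)
    ids = G.ids
    genes = pd.DataFrame({
        "gene": ["gA", "gB"], "chrom": ["1", "2"],
        "start": [1_300_000, 1_300_000], "end": [1_320_000, 1_320_000],
        "tf": [False, False],
    })
    vals = pd.DataFrame(rng.normal(7, 1, size=(2, n)), index=["gA", "gB"], columns=ids)
    vals.loc["gA"] += 1.2 * codes[:, 2]       # eSNP at 1.5 Mb on chrom 1
    meta = pd.DataFrame({
        "batch": rng.integers(1, 3, n),
        "laboratory": rng.integers(1, 3, n),
        "group": ["none"] * n,
    }, index=ids)
    em = ExpressionMatrix(values=vals, sample_meta=meta,
                          detection=vals.notna())
    return G, em, genes


class TestEgwas:
    def test_cis_trans_boundary_labels(self):
        G, em, genes = _tiny_expression()
        K = Grm(np.eye(len(em.samples)), em.samples, "per-snp-standardized", 6)
        res = egwas_scan(em, ["gA", "gB"], K, G, annotation=genes)
        a = res[res["gene"] == "gA"].set_index("snp")
        # gene gA starts at 1.3 Mb on chrom 1; window is +-1 Mb inclusive
        assert a.loc["s0", "cis_trans"] == "trans"   # 1.2 Mb away
        assert a.loc["s1", "cis_trans"] == "cis"     # 0.4 Mb
        assert a.loc["s2", "cis_trans"] == "cis"     # 0.2 Mb
        assert a.loc["s4", "cis_trans"] == "trans"   # 1.7 Mb
        b = res[res["gene"] == "gB"]
        assert (b["cis_trans"] == "trans").all()     # different chromosome

    def test_exact_one_mb_is_cis(self):
        G, em, genes = _tiny_expression()
        genes = genes.copy()
        genes.loc[0, "start"] = 2_500_000            # s0 at 100 kb: 2.4 Mb trans
        K = Grm(np.eye(len(em.samples)), em.samples, "per-snp-standardized", 6)
        res = egwas_scan(em, ["gA"], K, G, annotation=genes)
        a = res.set_index("snp")
        assert a.loc["s2", "cis_trans"] == "cis"     # exactly 1.0 Mb away
        assert a.loc["s0", "cis_trans"] == "trans"

    def test_missing_gene_listed(self):
        G, em, genes = _tiny_expression()
        K = Grm(np.eye(len(em.samples)), em.samples, "per-snp-standardized", 6)
        with pytest.raises(ValueError, match="gZ"):
            egwas_scan(em, ["gZ"], K, G, annotation=genes)

    def test_qvalues_within_gene(self):
        G, em, genes = _tiny_expression()
        K = Grm(np.eye(len(em.samples)), em.samples, "per-snp-standardized", 6)
        res = egwas_scan(em, ["gA"], K, G, annotation=genes)
        assert np.allclose(res["q"], bh_qvalues(res["p"].to_numpy()), atol=1e-12)
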