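"""Reusable study-condition experiments.

These functions run the pipeline's statistical checks at the study's design
points (350 animals, 5 half-sib families, the array-scale SNP densities
scaled to desk size) and return the summary quantities. They are shared by
the test suite and the acceptance script so that every reported number is
recomputed from scratch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from fenet import expr as expr_mod
from fenet import gwas as gwas_mod
from fenet import predict as predict_mod
from fenet.pheno import derive_traits, qc_genotypes
from fenet.simdata import (
    SimConfig,
    simulate_expression,
    simulate_genetic_values,
    simulate_phenotypes,
    simulate_population,
)

__all__ = [
    "h2_recovery",
    "prediction_ordering",
    "de_null_calibration",
    "cis_eqtl_power",
    "rfi_mean_abs",
]


def _simulate_single_trait(seed: int, n_snps: int, qtl: int, h2: float,
                           n_individuals: int = 350):
    """Population + single heritable trait with a known causal SNP set."""
    cfg = SimConfig(
        n_individuals=n_individuals, n_families=5, n_snps=n_snps,
        n_chromosomes=min(18, max(5, n_snps // 250)),
        qtl_per_trait=qtl, qtl_variance_fraction=1.0, pleiotropy_fraction=0.0,
        seed=seed,
    )
    pop = simulate_population(cfg)
    G, _ = qc_genotypes(pop.genotypes)
    rng = np.random.default_rng([seed, 7])
    bv, eff = simulate_genetic_values(G, cfg, rng, traits=("RFI",))
    causal = list(eff.index[eff["RFI"].to_numpy() != 0])
    n = G.n_individuals
    g = bv["RFI"].to_numpy() * np.sqrt(h2)
    X = np.column_stack([np.ones(n), rng.uniform(121, 148, n)])
    y = X @ np.array([2.0, 0.005]) + g + rng.standard_normal(n) * np.sqrt(1 - h2)
    return pop, G, X, y, causal


def rfi_mean_abs(seed: int = 0, n_individuals: int = 200, n_snps: int = 800) -> float:
    """|mean RFI| after trait derivation on a fresh synthetic table."""
    cfg = SimConfig(n_individuals=n_individuals, n_families=5, n_snps=n_snps,
                    n_chromosomes=6, seed=seed)
    pop = simulate_population(cfg)
    ph, _ = simulate_phenotypes(pop.genotypes, pop.pedigree, cfg)
    derived, _ = derive_traits(ph)
    return float(abs(derived["RFI"].mean()))


def h2_recovery(n_seeds: int = 20, h2: float = 0.5, seed: int = 0,
                iters: int = 20_000, n_snps: int = 1200) -> dict:
    """Posterior-mean h2 of a Gibbs animal model averaged over simulations.

    Truth: 350 offspring of 5 sires, polygenic trait from 300 QTL, fitted
    with the genomic relationship matrix and a scaled chain.
    """
    means = []
    for s in range(n_seeds):
        _, G, X, y, _ = _simulate_single_trait(seed * 1009 + s, n_snps, 300, h2)
        K = gwas_mod.compute_grm(G).matrix
        res = predict_mod.gibbs_variance(
            y, X, K, iters=iters, burnin=iters // 10, thin=10, seed=seed * 31 + s,
            matrix_tag="K(all)",
        )
        means.append(res.h2)
    return {"mean_h2": float(np.mean(means)), "per_seed": means,
            "truth": h2, "n_seeds": n_seeds}


def prediction_ordering(n_reps: int = 20, seed: int = 0, n_snps: int = 5000,
                        qtl: int = 800, h2: float = 0.6,
                        gibbs_iters: int = 5000) -> dict:
    """Cross-validated accuracy of causal-panel K vs all-SNP K vs pedigree A.

    Per study replicate: fresh population and trait, variance components per
    relationship matrix from a scaled Gibbs chain on the full data, 20
    random ~88/12 validation splits. Returns per-replicate accuracies and
    the fraction of replicates where the causal panel beats both baselines
    by at least 0.05.
    """
    rows = []
    for rep in range(n_reps):
        pop, G, X, y, causal = _simulate_single_trait(seed * 2003 + rep, n_snps, qtl, h2)
        A, _ = predict_mod.pedigree_A(pop.pedigree, ids=G.ids)
        panels = {
            "pedigree": A,
            "all_snps": gwas_mod.compute_grm(G).matrix,
            "causal": gwas_mod.compute_grm(G, subset=causal).matrix,
        }
        accs = {}
        for tag, R in panels.items():
            vc = predict_mod.gibbs_variance(
                y, X, R, iters=gibbs_iters, burnin=gibbs_iters // 5, thin=5,
                seed=seed * 17 + rep, matrix_tag=tag,
            )
            cv = predict_mod.cross_validate(
                y, X, R, vc.sigma2_u, vc.sigma2_e, n_rep=20,
                seed=seed * 13 + rep, matrix_tag=tag,
            )
            accs[tag] = cv.mean
        rows.append(accs)
    df = pd.DataFrame(rows)
    wins = ((df["causal"] - df["all_snps"] >= 0.05)
            & (df["causal"] - df["pedigree"] >= 0.05))
    return {
        "accuracies": df,
        "mean_accuracy": df.mean().to_dict(),
        "win_fraction": float(wins.mean()),
        "n_reps": n_reps,
    }


def de_null_calibration(n_sims: int = 200, n_genes: int = 2000,
                        n_per_group: int = 10, seed: int = 0) -> dict:
    """False-discovery behaviour of the trend-moderated DE test under the
    global null (no planted group effect).

    Returns the observed FDR (mean of V/max(R,1) over simulations, which
    under a complete null is the fraction of simulations with any call) for
    the |FC| > 1.5 & q < 0.05 rule, plus the pooled raw-p rejection rate.
    """
    rng = np.random.default_rng(seed)
    any_call = []
    raw_rate = []
    n = 2 * n_per_group
    groups = np.array(["HFE"] * n_per_group + ["LFE"] * n_per_group)
    for _ in range(n_sims):
        baseline = rng.normal(7.0, 1.5, size=n_genes)
        noise_sd = rng.uniform(0.3, 0.7, size=n_genes)
        vals = baseline[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n)) * noise_sd[:, None]
        batch = rng.integers(1, 3, size=n)
        lab = rng.integers(1, 3, size=n)
        values = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame({"group": groups, "batch": batch, "laboratory": lab},
                            index=values.columns)
        res = expr_mod.de_trend_test(values, meta)
        n_calls = int(res.table["de"].sum())
        any_call.append(n_calls / max(n_calls, 1))
        raw_rate.append(float((res.table["p"] < 0.05).mean()))
    fdr = float(np.mean(any_call))
    se = float(np.std(any_call, ddof=1) / np.sqrt(n_sims))
    return {"observed_fdr": fdr, "se": se, "raw_p_rate": float(np.mean(raw_rate)),
            "n_sims": n_sims}


def cis_eqtl_power(n_sims: int = 50, n_expr: int = 104, n_snps: int = 500,
                   effect: float = 1.0, q_thresh: float = 0.05,
                   seed: int = 0) -> dict:
    """Detection rate of planted cis-eQTL at the study's expression sample size.

    Per simulation: a fresh population, two planted cis genes at
    ``effect`` log2 per allele, per-gene mixed-model eGWAS with laboratory
    effect, detection = any SNP within 1 Mb of the gene at q <= ``q_thresh``.
    """
    detected, total = 0, 0
    for s in range(n_sims):
        cfg = SimConfig(
            n_individuals=n_expr, n_families=5, n_snps=n_snps, n_chromosomes=5,
            n_genes_expressed=40, n_cis_eqtl=2, n_trans_eqtl=0, n_de_genes=0,
            eqtl_effect=effect, seed=seed * 4001 + s,
        )
        pop = simulate_population(cfg)
        G, _ = qc_genotypes(pop.genotypes)
        groups = pd.Series("none", index=G.ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            em, truth = simulate_expression(G, pop.annotation, groups, cfg)
        if truth.cis_eqtl.empty:
            continue
        K = gwas_mod.compute_grm(G)
        res = gwas_mod.egwas_scan(
            em, list(truth.cis_eqtl["gene"]), K, G,
            annotation=pop.annotation.genes,
        )
        for gene, snp in zip(truth.cis_eqtl["gene"], truth.cis_eqtl["snp"]):
            total += 1
            sub = res[(res["gene"] == gene) & (res["q"] <= q_thresh)
                      & (res["cis_trans"] == "cis")]
            if len(sub):
                detected += 1
    return {"power": detected / total if total else np.nan,
            "n_planted": total, "n_detected": detected, "n_sims": n_sims}
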