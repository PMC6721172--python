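"""One-command pipeline driver: simulate -> QC -> traits -> GWAS -> AWM ->
PCIT -> regulators -> expression analyses -> eGWAS -> prediction."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from fenet import awm as awm_mod
from fenet import expr as expr_mod
from fenet import gwas as gwas_mod
from fenet import pheno as pheno_mod
from fenet import predict as predict_mod
from fenet import regulators as reg_mod
from fenet.config import PipelineConfig
from fenet.io import write_pedigree, write_tsv
from fenet.simdata import ANALYSIS_TRAITS, SimConfig, simulate_expression, simulate_population, simulate_phenotypes

__all__ = ["run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


class PipelineResult(dict):
    """Stage outputs keyed by stage name; also carries the manifest."""


def _manifest_entry(manifest: dict, outdir: Path, stage: str, status: str, **info) -> None:
    manifest["stages"].append({"stage": stage, "status": status, **info})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute all enabled stages, writing per-stage TSV outputs and a
    manifest under ``outdir``. Halts on stage failure with the manifest
    recording the completed stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "started": time.strftime("%Y-%m-%d %H:%M:%S"),
                "stages": []}
    res = PipelineResult()
    res["manifest"] = manifest
    try:
        _run(config, outdir, manifest, res)
    except Exception as exc:  # record the failure point, then re-raise
        _manifest_entry(manifest, outdir, "FAILED", f"{type(exc).__name__}: {exc}")
        raise
    return res


def _run(config: PipelineConfig, outdir: Path, manifest: dict, res: PipelineResult) -> None:
    cfg = config

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
    pop = simulate_population(sim_cfg)
    pheno_raw, truth = simulate_phenotypes(pop.genotypes, pop.pedigree, sim_cfg)
    write_pedigree(pop.pedigree, outdir / "pedigree.tsv")
    res["population"], res["pheno_truth"] = pop, truth
    _manifest_entry(manifest, outdir, "simulate", "ok",
                    n_individuals=pop.genotypes.n_individuals,
                    n_snps=pop.genotypes.n_snps)

    # --- QC ---------------------------------------------------------------
    G, qc_report = pheno_mod.qc_genotypes(
        pop.genotypes, maf_min=cfg.qc_maf_min, miss_max=cfg.qc_miss_max,
        hwe_p=cfg.qc_hwe_p,
    )
    res["genotypes"], res["qc_report"] = G, qc_report
    _manifest_entry(manifest, outdir, "qc", "ok", **qc_report.__dict__)

    # --- derive traits ----------------------------------------------------
    pheno, rfi_fit = pheno_mod.derive_traits(pheno_raw)
    write_tsv(pheno.reset_index(names="id"), outdir / "phenotypes.tsv")
    res["phenotypes"], res["rfi_fit"] = pheno, rfi_fit
    _manifest_entry(manifest, outdir, "derive-traits", "ok", n_records=len(pheno))

    # --- GWAS x 9 ---------------------------------------------------------
    K = gwas_mod.compute_grm(G)
    X = gwas_mod.design_matrix(pheno, batch="batch", covariates=("age_slaughter",))
    scans: dict[str, pd.DataFrame] = {}
    for t in ANALYSIS_TRAITS:
        y = pheno[t].to_numpy(float)
        vc = gwas_mod.fit_null_model(y, X, K)
        scans[t] = gwas_mod.assoc_scan(y, X, K, G, vc, trait=t)
        write_tsv(scans[t], outdir / f"gwas_{t}.tsv")
    res["grm"], res["scans"] = K, scans
    _manifest_entry(manifest, outdir, "gwas", "ok", traits=len(scans))

    # --- AWM --------------------------------------------------------------
    awm = awm_mod.select_awm_snps(
        scans, pop.annotation, key_trait=cfg.awm_key_trait,
        p_thresh=cfg.awm_p_thresh, min_other=cfg.awm_min_other,
        max_dist=cfg.awm_max_dist,
    )
    write_tsv(awm.z.join(awm.provenance).reset_index(names="snp"), outdir / "awm.tsv")
    corr, link, newick = awm_mod.trait_structure(awm)
    write_tsv(corr.reset_index(names="trait"), outdir / "trait_correlations.tsv")
    (outdir / "trait_dendrogram.nwk").write_text(newick + "\n")
    res["awm"], res["trait_corr"], res["trait_newick"] = awm, corr, newick
    _manifest_entry(manifest, outdir, "awm", "ok", n_snps=len(awm.z))

    # --- PCIT -------------------------------------------------------------
    labels = dict(zip(awm.provenance.index, awm.provenance["gene"]))
    net = awm_mod.pcit(awm, aggregation=cfg.pcit_aggregation, labels=labels)
    write_tsv(net.edges, outdir / "network_edges.tsv")
    degree_table, tf_table, mean_degree = awm_mod.hub_ranking(net, pop.annotation)
    write_tsv(degree_table, outdir / "node_degrees.tsv")
    res["network"], res["hubs"] = net, (degree_table, tf_table, mean_degree)
    _manifest_entry(manifest, outdir, "pcit", "ok", n_nodes=len(net.nodes),
                    n_edges=len(net.edges), mean_degree=round(mean_degree, 2))

    # --- regulators -------------------------------------------------------
    tf_nodes = list(tf_table["node"])
    reg_out = {}
    if len(tf_nodes) >= 4:
        for k in (3, 4):
            cap = tf_nodes[:40] if len(tf_nodes) > 40 else tf_nodes
            reg_out[k] = reg_mod.lossless_search(net, cap, k=k, top_n=10)
            write_tsv(reg_mod.regulator_table(reg_out[k], labels),
                      outdir / f"regulators_k{k}.tsv")
    res["regulators"] = reg_out
    _manifest_entry(manifest, outdir, "regulators", "ok",
                    n_tf=len(tf_nodes))

    # --- expression stages ------------------------------------------------
    candidates = None
    expr_matrix = None
    if cfg.run_expression:
        rng = np.random.default_rng([cfg.seed, 101])
        groups_all = expr_mod.assign_fe_groups(pheno["RFI"], cfg.n_extreme_per_group)
        extremes = groups_all[groups_all != "none"].index
        others = [i for i in pheno.index if i not in set(extremes)]
        n_extra = max(min(cfg.n_expression_samples, len(pheno)) - len(extremes), 0)
        extra = list(rng.choice(others, size=n_extra, replace=False))
        expr_ids = list(extremes) + extra
        groups = groups_all.loc[expr_ids]
        expr_matrix, expr_truth = simulate_expression(G, pop.annotation, groups, sim_cfg)
        res["expression"], res["expr_truth"] = expr_matrix, expr_truth

        detected = expr_mod.preprocess_expression(
            expr_matrix.values, expr_matrix.detection,
            pd.Series(expr_matrix.values.index, index=expr_matrix.values.index),
        )
        filtered = expr_matrix.__class__(
            values=detected, sample_meta=expr_matrix.sample_meta,
            detection=expr_matrix.detection.loc[detected.index],
        )
        de = expr_mod.de_trend_test(filtered, fc_thresh=cfg.de_fc_thresh,
                                    q_thresh=cfg.de_q_thresh)
        write_tsv(de.table, outdir / "de_results.tsv")

        spls = expr_mod.splsda_fit(
            filtered, ncomp=cfg.splsda_ncomp, keepX=cfg.splsda_keepX,
            folds=cfg.splsda_folds, reps=cfg.splsda_reps, seed=cfg.seed,
        )
        traits_x = pheno.loc[filtered.samples, ["RFI", "FCR", "ADG", "ADFI"]]
        rcca = expr_mod.rcca_fit(
            filtered.values, traits_x,
            lambda1=cfg.rcca_lambda1, lambda2=cfg.rcca_lambda2, key_trait="RFI",
        )
        cand_table, concordance = expr_mod.integrate_candidates(de, spls, rcca)
        write_tsv(cand_table, outdir / "candidate_genes.tsv")
        candidates = cand_table
        res["de"], res["splsda"], res["rcca"] = de, spls, rcca
        res["candidates"], res["loading_concordance"] = cand_table, concordance
        _manifest_entry(manifest, outdir, "expression", "ok",
                        n_genes=len(detected), n_de=int(de.table["de"].sum()),
                        n_candidates=int(cand_table["candidate"].sum()))
    else:
        _manifest_entry(manifest, outdir, "expression", "skipped")

    # --- eGWAS ------------------------------------------------------------
    esnps = []
    if cfg.run_egwas and cfg.run_expression:
        awm_genes = set(awm.provenance["gene"].dropna())
        cand_genes = set(candidates.loc[candidates["candidate"], "gene"])
        expressed = [g for g in detected.index if g in (awm_genes | cand_genes)]
        if not expressed:
            expressed = list(detected.index[: cfg.egwas_max_genes])
        expressed = expressed[: cfg.egwas_max_genes]
        egwas = gwas_mod.egwas_scan(
            filtered, expressed, K, G, annotation=pop.annotation.genes,
            cis_window=cfg.egwas_cis_window,
        )
        sig = egwas[egwas["q"] <= cfg.egwas_q_thresh].copy()
        write_tsv(sig, outdir / "esnps.tsv")
        esnps = sorted(set(sig["snp"]))
        res["egwas"], res["esnps"] = egwas, esnps
        _manifest_entry(manifest, outdir, "egwas", "ok", n_genes=len(expressed),
                        n_esnps=len(esnps))
    else:
        _manifest_entry(manifest, outdir, "egwas", "skipped")

    # --- prediction -------------------------------------------------------
    if cfg.run_prediction:
        y = pheno["RFI"].to_numpy(float)
        Xp = gwas_mod.design_matrix(pheno, batch="batch", covariates=("age_slaughter",))
        batch = pheno["batch"].to_numpy()
        A, _ = predict_mod.pedigree_A(pop.pedigree, ids=list(pheno.index))
        awm_snps = awm.snps
        panels: dict[str, np.ndarray] = {
            "pedigree": A,
            "all_snps": K.matrix,
        }
        if len(awm_snps) >= 10:
            panels["awm_snps"] = gwas_mod.compute_grm(G, subset=awm_snps).matrix
            combined = sorted(set(awm_snps) | set(esnps))
            if len(combined) > len(awm_snps):
                panels["awm_esnps"] = gwas_mod.compute_grm(G, subset=combined).matrix
        summary_rows = []
        for tag, R in panels.items():
            vc = predict_mod.gibbs_variance(
                y, Xp, R, iters=cfg.gibbs_iters, burnin=cfg.gibbs_burnin,
                thin=cfg.gibbs_thin, seed=cfg.seed, matrix_tag=tag,
            )
            cv = predict_mod.cross_validate(
                y, Xp, R, vc.sigma2_u, vc.sigma2_e, batch=batch,
                n_rep=cfg.cv_replicates, train_frac=cfg.cv_train_frac,
                seed=cfg.seed, matrix_tag=tag,
            )
            summary_rows.append({
                "panel": tag, "h2": vc.h2, "h2_sd": vc.sd_h2,
                "accuracy": cv.mean, "accuracy_sd": cv.sd,
            })
            res[f"gibbs_{tag}"], res[f"cv_{tag}"] = vc, cv
        summary = pd.DataFrame(summary_rows)
        write_tsv(summary, outdir / "prediction_summary.tsv")
        res["prediction_summary"] = summary
        _manifest_entry(manifest, outdir, "prediction", "ok",
                        panels=list(panels))
    else:
        _manifest_entry(manifest, outdir, "prediction", "skipped")

    manifest["finished"] = time.strftime("%Y-%m-%d %H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
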