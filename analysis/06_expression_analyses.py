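"""Muscle transcriptome analyses on the expression subset (104 pigs, 10 + 10
extreme-RFI animals): detection filtering, trend-moderated differential
expression LFE vs HFE, sparse PLS-DA discrimination, rCCA integration with
the feed-efficiency traits, and candidate-gene consolidation."""

from pathlib import Path

import numpy as np
import pandas as pd

from fenet import expr as ex
from fenet.io import read_ped_map, read_tsv, write_tsv
from fenet.simdata import SimConfig, SnpAnnotation, simulate_expression

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 1


def main() -> None:
    G = read_ped_map(OUT / "genotypes_qc")
    pheno = read_tsv(OUT / "phenotypes.tsv", index_col=0)
    annotation = SnpAnnotation(
        snp_genes=read_tsv(OUT / "snp_annotation.tsv"),
        genes=read_tsv(OUT / "gene_catalogue.tsv", dtype={"chrom": str}),
    )
    cfg = SimConfig(n_individuals=350, n_families=5, n_snps=5000,
                    n_genes_expressed=1500, seed=SEED)

    groups_all = ex.assign_fe_groups(pheno["RFI"], n_per_group=10)
    extremes = list(groups_all[groups_all != "none"].index)
    rng = np.random.default_rng([SEED, 101])
    others = [i for i in pheno.index if i not in set(extremes)]
    expr_ids = extremes + list(rng.choice(others, size=104 - len(extremes), replace=False))
    em, truth = simulate_expression(G, annotation, groups_all.loc[expr_ids], cfg)
    print(f"expression matrix: {len(em.genes)} genes x {len(em.samples)} samples "
          f"(two laboratories: {np.bincount(em.sample_meta['laboratory'])[1:]})")

    detected = ex.preprocess_expression(
        em.values, em.detection, pd.Series(em.values.index, index=em.values.index))
    em_f = em.__class__(values=detected, sample_meta=em.sample_meta,
                        detection=em.detection.loc[detected.index])
    print(f"{len(detected)} genes detected in >= 25% of samples "
          f"({len(em.genes) - len(detected)} discarded)")
    detected.reset_index().to_csv(OUT / "expression.tsv", sep="\t", index=False)
    em.sample_meta.reset_index(names="id").to_csv(OUT / "expression_samples.tsv",
                                                  sep="\t", index=False)

    de = ex.de_trend_test(em_f)
    write_tsv(de.table, OUT / "de_results.tsv")
    n_de = int(de.table["de"].sum())
    up_lfe = int((de.table["de"] & (de.table["fc"] > 0)).sum())
    top = de.table.loc[de.table["p"].idxmin()]
    print(f"DE (|FC| > 1.5, q < 0.05): {n_de} genes, {up_lfe} higher in LFE; "
          f"top gene {top['gene']} FC = {top['fc']:+.2f}, q = {top['q']:.1e}; "
          f"prior df = {de.prior_df:.1f}")

    spls = ex.splsda_fit(em_f, ncomp=2, keepX=[50, 50], reps=10, seed=SEED)
    print(f"sPLS-DA: BER = {spls.ber[1]:.2f} (comp 1), {spls.ber[2]:.2f} (comp 2); "
          f"{len(spls.selected[1])} genes on component 1")
    write_tsv(spls.loadings.reset_index(names="gene"), OUT / "splsda_loadings.tsv")

    traits_x = pheno.loc[em_f.samples, ["RFI", "FCR", "ADG", "ADFI"]]
    rcca = ex.rcca_fit(em_f.values, traits_x, key_trait="RFI")
    print(f"rCCA: canonical correlations {np.round(rcca.canonical_correlations, 2)}, "
          f"shrinkage lambdas ({rcca.lambdas[0]:.3f}, {rcca.lambdas[1]:.3f}); "
          f"{len(rcca.selected[1])} genes above the median + 2 SD rule "
          f"(threshold {rcca.threshold:.2f})")
    write_tsv(rcca.loadings.reset_index(names="gene"), OUT / "rcca_loadings.tsv")

    table, concordance = ex.integrate_candidates(de, spls, rcca)
    write_tsv(table, OUT / "candidate_genes.tsv")
    n_all3 = int((table["n_methods"] == 3).sum())
    print(f"candidates: {int(table['candidate'].sum())} genes by >= 2 methods "
          f"({n_all3} by all three); sPLS-DA/rCCA loading concordance r = {concordance:.2f}")


if __name__ == "__main__":
    main()
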