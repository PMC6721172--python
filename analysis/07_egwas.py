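"""Expression GWAS: SNPs associated with candidate-gene expression (eSNPs),
with batch and laboratory fixed effects, per-gene q <= 0.05 and cis/trans
labels at the 1 Mb window."""

from pathlib import Path

import pandas as pd

from fenet import gwas
from fenet.io import read_ped_map, read_tsv, write_tsv
from fenet.simdata import ExpressionMatrix

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
MAX_GENES = 40


def main() -> None:
    G = read_ped_map(OUT / "genotypes_qc")
    expr_vals = read_tsv(OUT / "expression.tsv", index_col=0)
    meta = read_tsv(OUT / "expression_samples.tsv", index_col=0)
    genes_cat = read_tsv(OUT / "gene_catalogue.tsv", dtype={"chrom": str})
    candidates = read_tsv(OUT / "candidate_genes.tsv")
    awm_genes = set(read_tsv(OUT / "awm.tsv")["gene"].dropna())

    cand = set(candidates.loc[candidates["candidate"], "gene"]) | awm_genes
    targets = [g for g in expr_vals.index if g in cand][:MAX_GENES]
    em = ExpressionMatrix(values=expr_vals, sample_meta=meta,
                          detection=expr_vals.notna())
    K = gwas.compute_grm(G)
    res = gwas.egwas_scan(em, targets, K, G, annotation=genes_cat)
    sig = res[res["q"] <= 0.05].copy()
    write_tsv(sig, OUT / "esnps.tsv")
    n_cis = int((sig["cis_trans"] == "cis").sum())
    print(f"eGWAS over {len(targets)} candidate genes expressed in muscle: "
          f"{sig['snp'].nunique()} eSNPs at q <= 0.05 for "
          f"{sig['gene'].nunique()} genes ({n_cis} cis, {len(sig) - n_cis} trans associations)")
    if len(sig):
        by_gene = sig.groupby("gene").size().sort_values(ascending=False)
        print("most associated genes: "
              + ", ".join(f"{g} ({n})" for g, n in by_gene.head(3).items()))
    pd.Series(sorted(sig["snp"].unique())).to_csv(OUT / "esnp_ids.txt",
                                                  index=False, header=False)


if __name__ == "__main__":
    main()
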