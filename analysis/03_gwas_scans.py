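"""Mixed-model GWAS for the nine analysed traits (RFI as key phenotype).

Model per SNP: y = batch + beta*age + u + s*a + e with u ~ N(0, G sigma2_u),
variance components from a REML null fit reused across SNPs (two-step scan).
One TSV of effects / SE / z / p per trait."""

from pathlib import Path

from fenet import gwas
from fenet.io import read_ped_map, read_tsv, write_tsv
from fenet.simdata import ANALYSIS_TRAITS

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    G = read_ped_map(OUT / "genotypes_qc")
    pheno = read_tsv(OUT / "phenotypes.tsv", index_col=0).loc[G.ids]
    K = gwas.compute_grm(G)
    X = gwas.design_matrix(pheno, batch="batch", covariates=("age_slaughter",))
    print(f"GRM from {K.n_snps} SNPs: diagonal mean "
          f"{K.matrix.diagonal().mean():.3f}")
    for t in ANALYSIS_TRAITS:
        y = pheno[t].to_numpy(float)
        vc = gwas.fit_null_model(y, X, K)
        res = gwas.assoc_scan(y, X, K, G, vc, trait=t)
        write_tsv(res, OUT / f"gwas_{t}.tsv")
        n_sig = int((res["p"] < 0.05).sum())
        print(f"  {t:5s}: REML h2 = {vc.h2:.2f}; "
              f"{n_sig} SNPs at nominal p < 0.05")


if __name__ == "__main__":
    main()
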