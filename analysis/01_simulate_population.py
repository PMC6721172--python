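"""Simulate the study population: 350 barrows from 5 paternal half-sib
families genotyped at 5,000 array SNPs, with the eight primary production
traits (feed intake assembled from metabolic weight, gain and backfat plus a
heritable residual-intake component).

Writes PLINK text genotypes, the pedigree, SNP annotation and the raw
phenotype table under results/analysis/.
"""

import sys
from pathlib import Path

from fenet.io import write_ped_map, write_pedigree, write_tsv
from fenet.simdata import SimConfig, simulate_phenotypes, simulate_population

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_individuals=350, n_families=5, n_snps=5000,
                    n_genes_expressed=1500, seed=seed)
    pop = simulate_population(cfg)
    pheno, truth = simulate_phenotypes(pop.genotypes, pop.pedigree, cfg)

    write_ped_map(pop.genotypes, OUT / "genotypes")
    write_pedigree(pop.pedigree, OUT / "pedigree.tsv")
    write_tsv(pop.annotation.snp_genes, OUT / "snp_annotation.tsv")
    write_tsv(pop.annotation.genes, OUT / "gene_catalogue.tsv")
    write_tsv(pheno.reset_index(names="id"), OUT / "phenotypes_raw.tsv")
    truth.breeding_values.reset_index(names="id").to_csv(
        OUT / "true_breeding_values.tsv", sep="\t", index=False)

    sires = pop.pedigree.sires()
    print(f"simulated {pop.genotypes.n_individuals} offspring of {len(sires)} sires, "
          f"{pop.genotypes.n_snps} SNPs on {cfg.n_chromosomes} chromosomes")
    print(f"mean MAF {pop.genotypes.maf().mean():.3f}; "
          f"phenotypes: {', '.join(c for c in pheno.columns if c not in ('sire', 'dam'))}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
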