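"""Association weight matrix and PCIT co-association network.

SNPs associated with RFI (p < 0.05) or with >= 3 other traits, within 10 kb
of a gene, enter the AWM of signed z-scores; trait clustering from AWM
columns; PCIT prunes row-row correlations explainable through a third SNP.
"""

import warnings
from pathlib import Path

import pandas as pd

from fenet import awm as am
from fenet.io import read_tsv, write_tsv
from fenet.simdata import ANALYSIS_TRAITS, SnpAnnotation

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    scans = {t: read_tsv(OUT / f"gwas_{t}.tsv", dtype={"chrom": str})
             for t in ANALYSIS_TRAITS}
    annotation = SnpAnnotation(
        snp_genes=read_tsv(OUT / "snp_annotation.tsv", dtype={"gene": str}),
        genes=read_tsv(OUT / "gene_catalogue.tsv", dtype={"chrom": str}),
    )
    matrix = am.select_awm_snps(scans, annotation)
    n_key = int(matrix.provenance["key_significant"].sum())
    print(f"AWM: {len(matrix.z)} SNPs retained "
          f"({n_key} via the RFI arm, {len(matrix.z) - n_key} via the >=3-trait arm)")
    write_tsv(matrix.z.join(matrix.provenance).reset_index(names="snp"), OUT / "awm.tsv")

    corr, link, newick = am.trait_structure(matrix)
    write_tsv(corr.reset_index(names="trait"), OUT / "awm_trait_correlations.tsv")
    (OUT / "trait_dendrogram.nwk").write_text(newick + "\n")
    print(f"AWM trait correlations: r(RFI,FCR) = {corr.loc['RFI', 'FCR']:.2f}, "
          f"r(ADFI,ADG) = {corr.loc['ADFI', 'ADG']:.2f}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # 9-point correlations: expected notice
        net = am.pcit(matrix)
    degree, tf_table, mean_deg = am.hub_ranking(net, annotation)
    write_tsv(net.edges, OUT / "network_edges.tsv")
    write_tsv(degree, OUT / "node_degrees.tsv")
    pd.Series(tf_table["node"]).to_csv(OUT / "tf_nodes.txt", index=False, header=False)
    print(f"PCIT network: {len(net.nodes)} nodes, {len(net.edges)} significant edges, "
          f"mean degree {mean_deg:.1f}")
    if len(tf_table):
        top = tf_table.iloc[0]
        print(f"{len(tf_table)} TF nodes; most connected TF: {top['gene']} "
              f"({top['degree']} interactions)")


if __name__ == "__main__":
    main()
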