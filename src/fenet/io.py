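"""File formats: PLINK text/binary genotypes, TSV tables, edge lists, Newick.

Coordinates are 1-based inclusive throughout the package; BED-style 0-based
half-open intervals are converted at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fenet.simdata import GenotypeMatrix, Pedigree

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "read_bed",
    "write_pedigree",
    "read_pedigree",
    "write_tsv",
    "read_tsv",
    "bed_to_annotation_rows",
]


def write_ped_map(G: GenotypeMatrix, prefix: str | Path, pheno: pd.Series | None = None) -> None:
    """Write PLINK text .ped/.map (alleles from snp_meta a1/a2; missing '0 0')."""
    prefix = Path(prefix)
    meta = G.snp_meta
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in meta.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")
    a1 = meta["a1"].to_numpy()
    a2 = meta["a2"].to_numpy()
    lookup = np.empty((4,), dtype=object)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(G.ids):
            ph = pheno.get(iid, -9) if pheno is not None else -9
            fields = ["FAM", iid, "0", "0", "0", str(ph)]
            codes = G.codes[i]
            geno = np.where(
                codes == 2, a1 + " " + a1,
                np.where(codes == 1, a1 + " " + a2,
                         np.where(codes == 0, a2 + " " + a2, "0 0")),
            )
            fh.write(" ".join(fields) + " " + " ".join(geno) + "\n")
    del lookup


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a GenotypeMatrix (codes count allele a1,
    defined as the first allele observed per SNP)."""
    prefix = Path(prefix)
    meta = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str},
    ).drop(columns="cm")
    m = len(meta)
    ids, rows = [], []
    a1 = np.array([""] * m, dtype=object)
    a2 = np.array([""] * m, dtype=object)
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError("malformed .ped line (allele count mismatch)")
            ids.append(parts[1])
            al = np.array(parts[6:], dtype=object).reshape(m, 2)
            called = (al[:, 0] != "0") & (al[:, 1] != "0")
            fill1 = (a1 == "") & called
            a1[fill1] = al[fill1, 0]
            for col in (0, 1):
                fill2 = (a2 == "") & called & (al[:, col] != a1)
                a2[fill2] = al[fill2, col]
            codes = np.where(
                called, (al[:, 0] == a1).astype(int) + (al[:, 1] == a1), -1
            ).astype(np.int8)
            rows.append(codes)
    a2 = np.where(a2 == "", "0", a2)
    meta["a1"] = a1
    meta["a2"] = a2
    G = GenotypeMatrix(np.vstack(rows), ids, meta)
    meta["maf"] = G.maf()
    return G


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK binary .bed/.bim/.fam (SNP-major). Codes count A1 copies."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    ).drop(columns="cm")
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[0] != 0x6C or raw[1] != 0x1B or raw[2] != 0x01:
        raise ValueError("not a SNP-major PLINK .bed file")
    bytes_per_snp = -(-n // 4)
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit fields: 00->2 copies of A1, 10->1, 11->0, 01->missing
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, -1)[:, :n]
    codes = np.select(
        [two_bit == 0, two_bit == 2, two_bit == 3], [2, 1, 0], default=-1
    ).astype(np.int8).T
    meta = bim.copy()
    G = GenotypeMatrix(codes, list(fam["iid"]), meta)
    meta["maf"] = G.maf()
    return G


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", dtype=str))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def bed_to_annotation_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a BED-like (0-based half-open) gene table to 1-based inclusive."""
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    return out
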