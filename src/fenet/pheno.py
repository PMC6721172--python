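"""Genotype quality control and derivation of the feed-efficiency phenotypes.

Residual feed intake (RFI) is the residual of a least-squares regression of
average daily feed intake on batch intercepts, a global age covariate, and
metabolic weight, average daily gain and backfat — the latter three with
partial regression coefficients nested within batch. Feed conversion ratio
(FCR) is the ratio of intake to gain, and metabolic weight is body weight
raised to the 0.75 power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fenet.simdata import GenotypeMatrix

__all__ = ["QcReport", "RfiFit", "qc_genotypes", "derive_traits", "hwe_pvalues"]

log = logging.getLogger(__name__)


@dataclass
class QcReport:
    n_input: int
    removed_missing: int
    removed_maf: int
    removed_hwe: int
    removed_unmapped: int
    removed_x: int
    n_retained: int


@dataclass
class RfiFit:
    """Fitted RFI regression: coefficients and residuals."""

    coef: pd.Series            # named design coefficients
    residuals: pd.Series       # = RFI, indexed by individual
    design: pd.DataFrame       # the design matrix used (for orthogonality checks)


def hwe_pvalues(G: GenotypeMatrix, exact: bool = False) -> np.ndarray:
    """Per-SNP Hardy-Weinberg p-values from genotype counts.

    Default is the 1-df chi-square goodness-of-fit test on the three genotype
    counts; ``exact=True`` switches to a mid-p-free exact test by full
    enumeration of heterozygote counts (small n only).
    """
    codes = G.codes
    n0 = (codes == 0).sum(axis=0).astype(float)
    n1 = (codes == 1).sum(axis=0).astype(float)
    n2 = (codes == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)  # monomorphic: conforms trivially
    if not exact:
        return stats.chi2.sf(chi2, df=1)
    out = np.empty(G.n_snps)
    for k in range(G.n_snps):
        out[k] = _hwe_exact(int(n1[k]), int(2 * n2[k] + n1[k]), int(n[k]))
    return out


def _hwe_exact(n_het: int, n_minor_alleles: int, n: int) -> float:
    """Exact HWE test: sum of heterozygote-count probabilities <= observed."""
    from math import comb, factorial

    n_a = min(n_minor_alleles, 2 * n - n_minor_alleles)
    denom = comb(2 * n, n_a)
    probs: dict[int, float] = {}
    for h in range(n_a % 2, n_a + 1, 2):
        hom_min = (n_a - h) // 2
        hom_maj = n - h - hom_min
        if hom_maj < 0:
            continue
        probs[h] = (
            factorial(n)
            / (factorial(hom_min) * factorial(h) * factorial(hom_maj))
            * 2**h
            / denom
        )
    obs = probs.get(n_het, 0.0)
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)))


def qc_genotypes(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.10,
    hwe_p: float = 0.001,
    drop_unmapped: bool = True,
    drop_x: bool = True,
    hwe_exact: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs (missingness -> MAF -> HWE -> unmapped/X) and impute.

    Thresholds are strict inequalities: a SNP is removed when its missing
    rate is *higher than* ``miss_max``, its MAF is *lower than* ``maf_min``,
    or its HWE p-value is below ``hwe_p``. Surviving missing genotypes are
    imputed to the per-SNP mean dosage rounded to the nearest integer code,
    which preserves allele frequency for relationship-matrix building.
    """
    n_input = G.n_snps
    keep = np.ones(n_input, dtype=bool)

    miss = G.missing_rate()
    fail_miss = miss > miss_max
    keep &= ~fail_miss

    maf = G.maf()
    fail_maf = keep & (maf < maf_min)
    keep &= ~fail_maf

    hwe = hwe_pvalues(G, exact=hwe_exact)
    fail_hwe = keep & (hwe < hwe_p)
    keep &= ~fail_hwe

    chrom = G.snp_meta["chrom"].astype(str)
    fail_unmapped = keep & chrom.isin(["0", "", "NA"]).to_numpy() if drop_unmapped else np.zeros(n_input, bool)
    keep &= ~fail_unmapped
    fail_x = keep & chrom.str.upper().isin(["X", "23"]).to_numpy() if drop_x else np.zeros(n_input, bool)
    keep &= ~fail_x

    if not keep.any():
        raise ValueError("no SNPs survive quality control")

    out = G.subset_snps(keep)
    # mean-dosage imputation of remaining missing genotypes
    codes = out.codes.astype(np.int8).copy()
    missing = codes == -1
    if missing.any():
        dose = out.dosage()
        means = np.nanmean(dose, axis=0)
        fill = np.clip(np.rint(means), 0, 2).astype(np.int8)
        codes = np.where(missing, fill[None, :], codes)
    out = GenotypeMatrix(codes, out.ids, out.snp_meta.reset_index(drop=True))
    out.snp_meta["maf"] = out.maf()

    report = QcReport(
        n_input=n_input,
        removed_missing=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_unmapped=int(fail_unmapped.sum()),
        removed_x=int(fail_x.sum()),
        n_retained=int(keep.sum()),
    )
    log.info("QC: %s", report)
    return out, report


def _rfi_design(table: pd.DataFrame) -> pd.DataFrame:
    """Design for the RFI regression: batch intercepts, global age covariate,
    and MW/ADG/BF nested within batch."""
    batches = sorted(table["batch"].unique())
    cols = {}
    for b in batches:
        ind = (table["batch"] == b).astype(float)
        cols[f"batch_{b}"] = ind
        cols[f"MW:batch_{b}"] = ind * table["MW"]
        cols[f"ADG:batch_{b}"] = ind * table["ADG"]
        cols[f"BF:batch_{b}"] = ind * table["BF"]
    cols["age_mid"] = table["age_mid"].astype(float)
    return pd.DataFrame(cols, index=table.index)


def derive_traits(table: pd.DataFrame) -> tuple[pd.DataFrame, RfiFit]:
    """Compute metabolic weight, FCR and RFI on a phenotype table.

    Requires columns ``ADFI, ADG, BF, BW, batch, age_mid``. Returns a copy of
    the table with ``MW``, ``FCR`` and ``RFI`` columns and the fitted RFI
    regression. Raises on non-positive gain (FCR undefined) and on a
    rank-deficient nested design (e.g. a batch with too few individuals).
    """
    required = ["ADFI", "ADG", "BF", "BW", "batch", "age_mid"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    counts = table["batch"].value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 individuals")
    if (table["ADG"] <= 0).any():
        bad = table.index[table["ADG"] <= 0][:5].tolist()
        raise ValueError(f"non-positive ADG for {bad}: FCR undefined")

    out = table.copy()
    out["MW"] = out["BW"] ** 0.75
    out["FCR"] = out["ADFI"] / out["ADG"]

    X = _rfi_design(out)
    y = out["ADFI"].to_numpy(float)
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        raise ValueError(
            f"RFI design is rank-deficient (rank {rank} < {Xv.shape[1]}): "
            "a batch has fewer individuals than nested coefficients"
        )
    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    out["RFI"] = resid
    fit = RfiFit(
        coef=pd.Series(beta, index=X.columns),
        residuals=pd.Series(resid, index=out.index, name="RFI"),
        design=X,
    )
    return out, fit
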