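"""Mixed-model association scans and genomic relationship matrices.

The scan uses the standard two-step approximation: variance components
(sigma2_u for the polygenic term under a genomic relationship matrix, and the
residual sigma2_e) are estimated once by REML on the null model via spectral
decomposition of the relationship matrix; each SNP effect is then estimated
by generalized least squares with the covariance V = K*sigma2_u + I*sigma2_e
held fixed. Expression scans (eGWAS) add a laboratory fixed effect and
per-gene Benjamini-Hochberg q-values with cis/trans labelling at a 1 Mb
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fenet.simdata import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "Grm",
    "VarianceComponents",
    "compute_grm",
    "fit_null_model",
    "assoc_scan",
    "egwas_scan",
    "bh_qvalues",
    "design_matrix",
]


@dataclass
class Grm:
    """Symmetric genomic relationship matrix with provenance."""

    matrix: np.ndarray
    ids: list[str]
    method: str
    n_snps: int
    ridged: bool = False

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    boundary: bool            # optimizer pinned at the search boundary
    identifiable: bool        # False when K ~ I and the split is not estimable
    # rotated quantities cached for reuse in the scan
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)


def compute_grm(
    G: GenotypeMatrix,
    subset: list[str] | None = None,
    method: str = "per-snp-standardized",
) -> Grm:
    """Genomic relationship matrix from 0/1/2 genotype codes.

    ``per-snp-standardized``: (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) /
    (2 p_k (1 - p_k)); ``overall-scaled``: cross-product of centered
    genotypes divided by sum_k 2 p_k (1 - p_k). Monomorphic SNPs in the
    subset raise (zero variance).
    """
    if method not in ("per-snp-standardized", "overall-scaled"):
        raise ValueError(f"unknown GRM method: {method}")
    if subset is not None:
        wanted = set(subset)
        mask = G.snp_meta["snp"].isin(wanted).to_numpy()
        if mask.sum() != len(wanted):
            missing = wanted - set(G.snp_meta["snp"])
            raise ValueError(f"subset SNPs absent from genotypes: {sorted(missing)[:5]}")
        G = G.subset_snps(mask)
    X = G.dosage()
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    p = X.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    if (het <= 0).any():
        bad = G.snp_meta["snp"][het <= 0].tolist()[:5]
        raise ValueError(f"monomorphic SNPs in GRM subset: {bad}")
    Z = X - 2.0 * p
    if method == "per-snp-standardized":
        Zs = Z / np.sqrt(het)
        M = (Zs @ Zs.T) / G.n_snps
    else:
        M = (Z @ Z.T) / het.sum()
    M = (M + M.T) / 2.0
    ridged = False
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8:
        M = M + np.eye(len(M)) * 1e-6
        ridged = True
    return Grm(M, list(G.ids), method, G.n_snps, ridged)


def design_matrix(
    meta: pd.DataFrame,
    batch: str | None = "batch",
    covariates: tuple[str, ...] = ("age_slaughter",),
    factors: tuple[str, ...] = (),
) -> np.ndarray:
    """Fixed-effect design: intercept, batch/factor dummies (first level
    dropped), numeric covariates."""
    n = len(meta)
    cols = [np.ones(n)]
    all_factors = ([batch] if batch else []) + list(factors)
    for f in all_factors:
        levels = sorted(pd.unique(meta[f]))
        for lev in levels[1:]:
            cols.append((meta[f] == lev).to_numpy(float))
    for c in covariates:
        cols.append(meta[c].to_numpy(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return X


def _reml_loglik(log_ratio: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Restricted log-likelihood profile in delta = sigma2_e / sigma2_u,
    evaluated in the eigenbasis of K (EMMA-style)."""
    delta = np.exp(log_ratio)
    n, p = Xr.shape
    v = d + delta                     # proportional variances
    Xw = Xr / v[:, None]
    XtVX = Xr.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ yr)
    r = yr - Xr @ beta
    rss = float(r @ (r / v))
    df = n - p
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    ll = -0.5 * (
        df * np.log(2 * np.pi * rss / df)
        + df
        + np.sum(np.log(v))
        + logdet_xvx
    )
    return ll


def fit_null_model(y: np.ndarray, X: np.ndarray, K: Grm) -> VarianceComponents:
    """Single-component REML via spectral decomposition of K.

    Rotates data by the eigenvectors of K and optimizes the restricted
    likelihood in the variance ratio on a log grid refined by Brent search.
    Flags boundary solutions and the non-identifiable K ~ I case.
    """
    y = np.asarray(y, float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 observations to fit variance components")
    d, U = np.linalg.eigh(K.matrix)
    if d.min() < -1e-6:
        raise ValueError("relationship matrix is not PSD even after ridging")
    d = np.clip(d, 0.0, None)
    identifiable = not np.allclose(K.matrix, np.eye(n) * K.matrix[0, 0], atol=1e-8)
    if not identifiable:
        warnings.warn("K is (proportional to) the identity: sigma2_u and sigma2_e "
                      "are not separately identifiable", stacklevel=2)
    yr = U.T @ y
    Xr = U.T @ X

    lo, hi = np.log(1e-5), np.log(1e5)
    grid = np.linspace(lo, hi, 41)
    lls = [_reml_loglik(g, d, yr, Xr) for g in grid]
    g0 = grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, d, yr, Xr),
        bracket=None, bounds=(max(lo, g0 - 1.0), min(hi, g0 + 1.0)), method="bounded",
    )
    log_delta = float(res.x)
    boundary = log_delta <= lo + 0.25 or log_delta >= hi - 0.25
    delta = np.exp(log_delta)

    v = d + delta
    Xw = Xr / v[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    sigma2_u = float(r @ (r / v)) / (n - p)
    sigma2_e = sigma2_u * delta
    return VarianceComponents(
        sigma2_u=max(sigma2_u, 1e-12),
        sigma2_e=max(sigma2_e, 1e-12),
        boundary=boundary,
        identifiable=identifiable,
        eigvals=d,
        eigvecs=U,
    )


def _whiten(vc: VarianceComponents, arr: np.ndarray) -> np.ndarray:
    """Transform to a basis where V = K s2u + I s2e becomes the identity."""
    v = vc.eigvals * vc.sigma2_u + vc.sigma2_e
    return (vc.eigvecs.T @ arr) / np.sqrt(v)[..., None] if arr.ndim == 2 else (
        (vc.eigvecs.T @ arr) / np.sqrt(v)
    )


def assoc_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: Grm,
    G: GenotypeMatrix,
    vc: VarianceComponents | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Single-marker GLS scan under fixed variance components.

    Returns one row per SNP with the allele-substitution effect on the
    counted (a1) allele, its SE, the signed z-score and the two-sided Wald
    p-value. Monomorphic SNPs get an NA row with a reason code.
    """
    y = np.asarray(y, float)
    if vc is None:
        vc = fit_null_model(y, X, K)
    if vc.eigvecs is None:
        d, U = np.linalg.eigh(K.matrix)
        vc.eigvals, vc.eigvecs = np.clip(d, 0, None), U
    yw = _whiten(vc, y)
    Xw = _whiten(vc, X)
    # residualize against fixed effects once; each SNP then needs only a
    # simple regression of the residualized response on the residualized SNP
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    S = np.nan_to_num(G.dosage())
    Sw = _whiten(vc, S)
    S_res = Sw - Q @ (Q.T @ Sw)

    ssq = np.einsum("ij,ij->j", S_res, S_res)
    mono = ssq <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (S_res.T @ y_res) / ssq
        df = len(y) - X.shape[1] - 1
        rss = float(y_res @ y_res) - beta**2 * ssq
        # V is held fixed from the null fit; its scale is already absorbed,
        # so the residual scale factor keeps the OLS-degeneracy limit exact
        se = np.sqrt(np.maximum(rss, 0.0) / df / ssq)
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    freq = S.mean(axis=0) / 2.0
    res = pd.DataFrame({
        "snp": G.snp_meta["snp"].to_numpy(),
        "chrom": G.snp_meta["chrom"].to_numpy(),
        "pos": G.snp_meta["pos"].to_numpy(),
        "allele": G.snp_meta["a1"].to_numpy(),
        "maf": np.minimum(freq, 1 - freq),
        "effect": beta,
        "se": se,
        "z": z,
        "p": p,
    })
    res["reason"] = ""
    res.loc[mono, ["effect", "se", "z", "p"]] = np.nan
    res.loc[mono, "reason"] = "monomorphic"
    res.attrs["trait"] = trait
    return res


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    m = np.isfinite(p).sum()
    order = np.argsort(p)
    q = np.full_like(p, np.nan)
    ranked = p[order]
    adj = ranked * m / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    q[order] = np.minimum(adj, 1.0)
    return q


def egwas_scan(
    expr: ExpressionMatrix,
    gene_ids: list[str],
    K: Grm,
    G: GenotypeMatrix,
    annotation: pd.DataFrame | None = None,
    cis_window: int = 1_000_000,
    gene_position: str = "start",
) -> pd.DataFrame:
    """Per-gene mixed-model eGWAS with a laboratory fixed effect.

    For each gene: REML null fit, GLS scan, Benjamini-Hochberg q-values
    within the gene across SNPs, Bonferroni column, and cis/trans labels
    (cis when the SNP lies within ``cis_window`` bp of the gene position on
    the same chromosome). ``annotation`` must be the gene catalogue
    (columns gene, chrom, start, end) when labelling is wanted.
    """
    missing = [g for g in gene_ids if g not in set(expr.genes)]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:10]}")
    sample_ids = expr.samples
    if not set(sample_ids) <= set(G.ids):
        raise ValueError("expression individuals must be a subset of genotyped individuals")
    Gs = G.subset_individuals(sample_ids)
    idx = [K.ids.index(i) for i in sample_ids]
    Ks = Grm(K.matrix[np.ix_(idx, idx)], sample_ids, K.method, K.n_snps, K.ridged)
    X = design_matrix(expr.sample_meta, batch="batch", covariates=(), factors=("laboratory",))

    gene_info = None
    if annotation is not None:
        gene_info = annotation.set_index("gene")

    out = []
    for g in gene_ids:
        y = expr.values.loc[g].to_numpy(float)
        vc = fit_null_model(y, X, Ks)
        res = assoc_scan(y, X, Ks, Gs, vc, trait=g)
        res["gene"] = g
        res["q"] = bh_qvalues(res["p"].to_numpy())
        res["bonferroni"] = np.minimum(res["p"] * res["p"].notna().sum(), 1.0)
        if gene_info is not None and g in gene_info.index:
            gc = str(gene_info.loc[g, "chrom"])
            gp = int(gene_info.loc[g, gene_position])
            same = res["chrom"].astype(str) == gc
            close = (res["pos"] - gp).abs() <= cis_window
            res["cis_trans"] = np.where(same & close, "cis", "trans")
        else:
            res["cis_trans"] = ""
        out.append(res)
    return pd.concat(out, ignore_index=True)
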