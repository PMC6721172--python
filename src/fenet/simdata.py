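"""Synthetic population, phenotype and expression generator.

Emulates the design of a commercial Duroc feed-efficiency experiment: a few
hundred barrows from a handful of paternal half-sib families, distributed
over fattening batches in a partially balanced design, genotyped on a dense
SNP array, with nine correlated production traits and a muscle expression
profile on a subset of animals assayed in two laboratories.

Genotypes are built from block-structured founder haplotypes (a small
haplotype pool per LD block) transmitted Mendelianly from each sire and a
per-offspring unrelated dam, which yields realistic within-block LD and
half-sib relationship structure without a coalescent simulator.

Phenotypes follow an additive model: batch effect + age covariate + QTL
effects (a configurable fraction shared across designated trait groups to
induce pleiotropy) + a polygenic background over the remaining SNPs +
Gaussian residual, scaled so that the narrow-sense heritability of each
trait equals its target. Average daily feed intake is constructed
structurally from metabolic weight, gain and backfat plus a genetic
residual-intake component, so that residual feed intake (RFI) and feed
conversion ratio are *derived* downstream exactly as in the real analysis.

All randomness flows from a single integer seed; stage-level generators use
deterministic sub-streams of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "Pedigree",
    "SnpAnnotation",
    "Population",
    "ExpressionMatrix",
    "PhenoTruth",
    "ExprTruth",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_genetic_values",
    "simulate_expression",
    "PRIMARY_TRAITS",
    "ANALYSIS_TRAITS",
]

#: traits simulated directly (ADFI is assembled from MW/ADG/BF + intake residual)
PRIMARY_TRAITS = ("ADG", "BW", "BF", "CW", "KO", "LEAN", "IMF", "RFI")

#: the nine traits entering the multi-trait association analysis
ANALYSIS_TRAITS = ("RFI", "FCR", "ADFI", "ADG", "CW", "KO", "BF", "LEAN", "IMF")

# population means / phenotypic SDs on the scale of the study population
_TRAIT_SCALE = {
    "ADG": (0.89, 0.11),   # kg/day
    "BW": (122.0, 10.5),   # kg live weight at slaughter
    "BF": (24.0, 4.9),     # mm
    "CW": (94.8, 10.6),    # kg
    "KO": (74.8, 2.4),     # %
    "LEAN": (40.8, 4.5),   # %
    "IMF": (5.23, 2.06),   # %
    "RFI": (0.0, 0.17),    # kg/day intake deviation
}

_DEFAULT_H2 = {
    "ADG": 0.40, "BW": 0.40, "BF": 0.45, "CW": 0.40,
    "KO": 0.30, "LEAN": 0.45, "IMF": 0.50, "RFI": 0.50,
}

# trait groups sharing pleiotropic QTL (effect correlation 1 within a group)
_DEFAULT_PLEIOTROPY_GROUPS = (
    ("ADG", "BW", "CW"),
    ("BF", "IMF"),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study population."""

    n_individuals: int = 350
    n_families: int = 5
    n_snps: int = 5000
    n_chromosomes: int = 18
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    n_traits: int = 9
    qtl_per_trait: int = 50
    pleiotropy_fraction: float = 0.5
    h2_per_trait: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_H2))
    pleiotropy_groups: tuple[tuple[str, ...], ...] = _DEFAULT_PLEIOTROPY_GROUPS
    qtl_variance_fraction: float = 0.6
    batch_count: int = 4
    n_genes_expressed: int = 2000
    n_cis_eqtl: int = 10
    n_trans_eqtl: int = 5
    n_de_genes: int = 100
    de_effect: float = 1.0
    eqtl_effect: float = 1.0
    expr_noise_sd: float = 0.5
    lab_count: int = 2
    lab_effect_mean: float = 0.0
    lab_effect_sd: float = 0.3
    tf_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_families > self.n_individuals:
            raise ValueError(
                f"n_families ({self.n_families}) exceeds n_individuals ({self.n_individuals})"
            )
        for name, v in self.h2_per_trait.items():
            if not (0.0 < v < 1.0):
                raise ValueError(f"h2 for {name} must be in (0,1), got {v}")
        for prop in ("pleiotropy_fraction", "tf_fraction", "qtl_variance_fraction"):
            v = getattr(self, prop)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{prop} must be in [0,1], got {v}")
        for count in ("n_individuals", "n_families", "n_snps", "n_chromosomes",
                      "ld_block_size", "batch_count", "lab_count"):
            if getattr(self, count) <= 0:
                raise ValueError(f"{count} must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes (0/1/2 copies of allele a1; -1 missing)."""

    codes: np.ndarray          # (n, m) int8
    ids: list[str]
    snp_meta: pd.DataFrame     # columns: snp, chrom, pos, a1, a2, maf

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.ids), len(self.snp_meta)):
            raise ValueError("genotype codes shape does not match ids / snp_meta")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed frequency of allele a1, ignoring missing codes."""
        codes = np.ma.masked_equal(self.codes, -1)
        return np.asarray(codes.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.codes == -1).mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes[:, mask],
            ids=list(self.ids),
            snp_meta=self.snp_meta.loc[mask].reset_index(drop=True),
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {v: k for k, v in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(self.codes[rows], list(ids), self.snp_meta.copy())

    def dosage(self) -> np.ndarray:
        """Float copy with missing codes as NaN."""
        out = self.codes.astype(float)
        out[out == -1] = np.nan
        return out


@dataclass
class Pedigree:
    """Pedigree table; founders carry unknown ('0') parents, parents precede offspring."""

    table: pd.DataFrame  # columns: id, sire, dam

    def __post_init__(self) -> None:
        seen: set[str] = {"0"}
        for row in self.table.itertuples(index=False):
            if row.sire not in seen or row.dam not in seen:
                raise ValueError(f"parent of {row.id} listed after it (or missing)")
            seen.add(row.id)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def sires(self) -> list[str]:
        s = self.table["sire"]
        return sorted(set(s[s != "0"]))


@dataclass
class SnpAnnotation:
    """Per-SNP nearest-gene records plus the gene catalogue itself."""

    snp_genes: pd.DataFrame   # snp, gene, distance (bp, 0 if inside), tf
    genes: pd.DataFrame       # gene, chrom, start, end, tf


@dataclass
class PhenoTruth:
    """Stored simulation truth for downstream recovery tests."""

    snp_effects: pd.DataFrame        # per trait: true (scaled) allele substitution effects
    breeding_values: pd.DataFrame    # per trait: true genetic values per individual
    batch_effects: pd.DataFrame
    age_slope: dict[str, float]


@dataclass
class ExprTruth:
    cis_eqtl: pd.DataFrame     # gene, snp, effect
    trans_eqtl: pd.DataFrame   # gene, snp, effect
    de_genes: list[str]
    lab_effects: pd.Series | None = None   # per-gene shift added to lab-2 samples


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with sample factors and detection flags."""

    values: pd.DataFrame       # genes x sample ids
    sample_meta: pd.DataFrame  # index sample ids: batch, laboratory, group
    detection: pd.DataFrame    # boolean, same shape as values

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Population:
    """Bundle returned by :func:`simulate_population`."""

    genotypes: GenotypeMatrix          # study offspring only
    pedigree: Pedigree                 # founders + offspring
    annotation: SnpAnnotation
    founder_genotypes: GenotypeMatrix  # sires and dams, for Mendelian checks
    config: SimConfig


# --------------------------------------------------------------------------
# population

def _snp_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    k = 0
    for c, n_c in enumerate(per_chrom, start=1):
        gaps = rng.integers(5_000, 60_000, size=n_c)
        pos = np.cumsum(gaps) + 10_000
        for p in pos:
            rows.append((f"snp{k:06d}", str(c), int(p)))
            k += 1
    meta = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    meta["a1"] = "A"
    meta["a2"] = "B"
    return meta


def _founder_haplotypes(cfg: SimConfig, n_founders: int, p: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_founders, 2, m) founder haplotypes with block-level LD from a
    haplotype pool; pool size scales with the founder count so that observed
    allele frequencies stay close to their targets."""
    m = len(p)
    pool_size = max(16, n_founders // 4)
    haps = np.empty((n_founders, 2, m), dtype=np.int8)
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        pool = (rng.random((pool_size, stop - start)) < p[start:stop]).astype(np.int8)
        picks = rng.integers(0, pool_size, size=(n_founders, 2))
        haps[:, :, start:stop] = pool[picks]
    return haps


def _gamete(haps: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    """One gamete: copy one of the two parental haplotypes per LD block."""
    m = haps.shape[1]
    n_blocks = -(-m // block)
    choice = rng.integers(0, 2, size=n_blocks)
    out = np.empty(m, dtype=np.int8)
    for b, c in enumerate(choice):
        s, e = b * block, min((b + 1) * block, m)
        out[s:e] = haps[c, s:e]
    return out


def _annotation(cfg: SimConfig, meta: pd.DataFrame, rng: np.random.Generator) -> SnpAnnotation:
    n_genes = max(cfg.n_genes_expressed, cfg.n_snps // 3, 10)
    chroms = meta["chrom"].unique()
    chrom_span = {c: int(meta.loc[meta.chrom == c, "pos"].max()) + 50_000 for c in chroms}
    weights = np.array([chrom_span[c] for c in chroms], dtype=float)
    gene_chrom = rng.choice(chroms, size=n_genes, p=weights / weights.sum())
    rows = []
    for g in range(n_genes):
        c = gene_chrom[g]
        start = int(rng.integers(1, chrom_span[c]))
        length = int(rng.integers(2_000, 50_000))
        rows.append((f"gene{g:05d}", c, start, start + length))
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    genes["tf"] = rng.random(n_genes) < cfg.tf_fraction

    recs = []
    for c, snps_c in meta.groupby("chrom", sort=False):
        gc = genes[genes.chrom == c]
        if gc.empty:
            continue
        starts = gc["start"].to_numpy()
        ends = gc["end"].to_numpy()
        mids = (starts + ends) / 2.0
        for snp, pos in zip(snps_c["snp"], snps_c["pos"]):
            j = int(np.argmin(np.abs(mids - pos)))
            if starts[j] <= pos <= ends[j]:
                dist = 0
            else:
                dist = int(min(abs(pos - starts[j]), abs(pos - ends[j])))
            recs.append((snp, gc["gene"].iloc[j], dist, bool(gc["tf"].iloc[j])))
    snp_genes = pd.DataFrame(recs, columns=["snp", "gene", "distance", "tf"])
    snp_genes = snp_genes.set_index("snp").reindex(meta["snp"]).reset_index()
    return SnpAnnotation(snp_genes=snp_genes, genes=genes)


def simulate_population(config: SimConfig) -> Population:
    """Simulate genotypes, pedigree and SNP annotation for a half-sib design.

    Founders (``n_families`` sires plus one unrelated dam per offspring) carry
    block-structured haplotypes; each offspring receives one recombinant gamete
    from its sire and one from its dam, so all genotypes are Mendelian by
    construction. Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 11])
    meta = _snp_map(cfg, rng)
    m = cfg.n_snps
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5          # allele a1 may be major or minor
    p = np.where(flip, 1.0 - p, p)

    n_sires = cfg.n_families
    n_dams = cfg.n_individuals
    founder_haps = _founder_haplotypes(cfg, n_sires + n_dams, p, rng)
    sire_haps = founder_haps[:n_sires]
    dam_haps = founder_haps[n_sires:]

    sire_ids = [f"sire{j + 1}" for j in range(n_sires)]
    dam_ids = [f"dam{j + 1:04d}" for j in range(n_dams)]
    off_ids = [f"pig{j + 1:04d}" for j in range(cfg.n_individuals)]

    # every sire gets at least one offspring; remainder assigned uniformly
    fam = np.concatenate([
        np.arange(n_sires),
        rng.integers(0, n_sires, size=cfg.n_individuals - n_sires),
    ])
    rng.shuffle(fam)

    codes = np.empty((cfg.n_individuals, m), dtype=np.int8)
    for i in range(cfg.n_individuals):
        g_s = _gamete(sire_haps[fam[i]], cfg.ld_block_size, rng)
        g_d = _gamete(dam_haps[i], cfg.ld_block_size, rng)
        codes[i] = g_s + g_d

    ped_rows = [(sid, "0", "0") for sid in sire_ids]
    ped_rows += [(did, "0", "0") for did in dam_ids]
    ped_rows += [
        (off_ids[i], sire_ids[fam[i]], dam_ids[i]) for i in range(cfg.n_individuals)
    ]
    pedigree = Pedigree(pd.DataFrame(ped_rows, columns=["id", "sire", "dam"]))

    meta = meta.copy()
    geno = GenotypeMatrix(codes=codes, ids=off_ids, snp_meta=meta)
    meta["maf"] = geno.maf()

    founder_codes = founder_haps.sum(axis=1).astype(np.int8)
    founders = GenotypeMatrix(founder_codes, sire_ids + dam_ids, meta.copy())
    annotation = _annotation(cfg, meta, rng)
    return Population(geno, pedigree, annotation, founders, cfg)


# --------------------------------------------------------------------------
# phenotypes

def simulate_genetic_values(
    G: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    traits: tuple[str, ...] = PRIMARY_TRAITS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True genetic values and scaled per-SNP effects for each trait.

    Each trait draws ``qtl_per_trait`` QTL; within a pleiotropy group a
    ``pleiotropy_fraction`` of them come from a shared pool with identical
    effects (effect correlation 1). The rest of the SNPs carry a small
    polygenic background. Genetic values are standardized to unit variance;
    the stored effects are on the same standardized scale.
    """
    cfg = config
    m = G.n_snps
    centered = G.dosage()
    centered = centered - np.nanmean(centered, axis=0)
    centered = np.nan_to_num(centered)

    group_of = {}
    for grp in cfg.pleiotropy_groups:
        for t in grp:
            group_of[t] = grp
    shared_pool: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}
    effects = {}
    n_shared = int(round(cfg.pleiotropy_fraction * cfg.qtl_per_trait))
    for t in traits:
        a = np.zeros(m)
        grp = group_of.get(t)
        if grp is not None and n_shared > 0:
            if grp not in shared_pool:
                idx = rng.choice(m, size=n_shared, replace=False)
                eff = rng.normal(0.0, 1.0, size=n_shared)
                shared_pool[grp] = (idx, eff)
            idx, eff = shared_pool[grp]
            a[idx] += eff
            n_private = cfg.qtl_per_trait - n_shared
        else:
            n_private = cfg.qtl_per_trait
        if n_private > 0:
            idx = rng.choice(m, size=n_private, replace=False)
            a[idx] += rng.normal(0.0, 1.0, size=n_private)
        # polygenic background on all SNPs, scaled to the target variance split
        poly = rng.normal(0.0, 1.0, size=m) / np.sqrt(m)
        g_qtl = centered @ a
        g_poly = centered @ poly
        sd_q = g_qtl.std() if g_qtl.std() > 0 else 1.0
        sd_p = g_poly.std() if g_poly.std() > 0 else 1.0
        w_q = np.sqrt(cfg.qtl_variance_fraction) if cfg.qtl_per_trait > 0 else 0.0
        w_p = np.sqrt(1.0 - cfg.qtl_variance_fraction) if cfg.qtl_per_trait > 0 else 1.0
        a_scaled = a * (w_q / sd_q) + poly * (w_p / sd_p)
        effects[t] = a_scaled
    eff_df = pd.DataFrame(effects, index=G.snp_meta["snp"])
    bv = pd.DataFrame(
        {t: centered @ eff_df[t].to_numpy() for t in traits}, index=G.ids
    )
    # exact standardization so downstream heritabilities hit their targets
    for t in traits:
        s = bv[t].std(ddof=0)
        if s > 0:
            eff_df[t] /= s
            bv[t] /= s
    return bv, eff_df


def _assign_batches(fam: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Partially balanced connected design: batch 1 holds all families, each
    later batch omits one family (cyclically)."""
    n = len(fam)
    batches = np.empty(n, dtype=int)
    for i in range(n):
        allowed = [0] + [
            b for b in range(1, cfg.batch_count)
            if cfg.n_families == 1 or (b - 1) % cfg.n_families != fam[i]
        ]
        batches[i] = allowed[rng.integers(0, len(allowed))]
    return batches + 1


def simulate_phenotypes(
    G: GenotypeMatrix, ped: Pedigree, config: SimConfig
) -> tuple[pd.DataFrame, PhenoTruth]:
    """Simulate the production phenotypes of the study design.

    Gain, body weight, backfat, carcass weight, killing-out, lean and
    intramuscular fat are simulated directly (batch + age + genetics +
    residual at the study's trait scales). Average daily feed intake is then
    assembled from batch-nested regressions on metabolic weight, gain and
    backfat plus a heritable residual-intake component, so that RFI and FCR
    are recovered by the downstream trait-derivation stage rather than being
    simulated outright.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 23])
    n = G.n_individuals
    ped_tab = ped.table.set_index("id")
    sires = [ped_tab.loc[i, "sire"] for i in G.ids]
    dams = [ped_tab.loc[i, "dam"] for i in G.ids]
    sire_index = {s: k for k, s in enumerate(sorted(set(sires)))}
    fam = np.array([sire_index[s] for s in sires])

    batch = _assign_batches(fam, cfg, rng)
    age_mid = rng.uniform(121.0, 148.0, size=n)          # days, trial midpoint
    age_slaughter = age_mid + rng.uniform(52.0, 58.0, size=n)

    bv, effects = simulate_genetic_values(G, cfg, rng)
    h2 = {**_DEFAULT_H2, **cfg.h2_per_trait}

    batch_effects = {}
    age_slopes = {}
    pheno = pd.DataFrame(index=G.ids)
    pheno["batch"] = batch
    pheno["age_mid"] = age_mid
    pheno["age_slaughter"] = age_slaughter
    pheno["sire"] = sires
    pheno["dam"] = dams

    for t in ("ADG", "BW", "BF", "CW", "KO", "LEAN", "IMF"):
        mu, sd = _TRAIT_SCALE[t]
        b_eff = rng.normal(0.0, 0.3 * sd, size=cfg.batch_count)
        slope = rng.normal(0.0, 0.01 * sd)
        g = bv[t].to_numpy() * np.sqrt(h2[t]) * sd
        e = rng.normal(0.0, np.sqrt(1.0 - h2[t]) * sd, size=n)
        pheno[t] = mu + b_eff[batch - 1] + slope * (age_mid - 135.0) + g + e
        batch_effects[t] = b_eff
        age_slopes[t] = slope

    # feed intake assembled structurally; nested coefficients vary by batch
    mu_fi, _ = 2.81, 0.37
    mw = pheno["BW"].to_numpy() ** 0.75
    gamma = 0.05 * (1.0 + rng.normal(0.0, 0.2, size=cfg.batch_count))
    delta_adg = 1.2 * (1.0 + rng.normal(0.0, 0.2, size=cfg.batch_count))
    delta_bf = 0.012 * (1.0 + rng.normal(0.0, 0.2, size=cfg.batch_count))
    b_eff_fi = rng.normal(0.0, 0.10, size=cfg.batch_count)
    alpha = 0.002
    mu_rfi, sd_rfi = _TRAIT_SCALE["RFI"]
    g_rfi = bv["RFI"].to_numpy() * np.sqrt(h2["RFI"]) * sd_rfi
    e_rfi = rng.normal(0.0, np.sqrt(1.0 - h2["RFI"]) * sd_rfi, size=n)
    rfi_true = mu_rfi + g_rfi + e_rfi
    pheno["ADFI"] = (
        mu_fi
        + b_eff_fi[batch - 1]
        + alpha * (age_mid - 135.0)
        + gamma[batch - 1] * (mw - mw.mean())
        + delta_adg[batch - 1] * (pheno["ADG"].to_numpy() - pheno["ADG"].mean())
        + delta_bf[batch - 1] * (pheno["BF"].to_numpy() - pheno["BF"].mean())
        + rfi_true
    )
    batch_effects["ADFI"] = b_eff_fi
    age_slopes["ADFI"] = alpha
    pheno["rfi_true"] = rfi_true

    # breeding values on the phenotype scale
    bv_scaled = bv.copy()
    for t in ("ADG", "BW", "BF", "CW", "KO", "LEAN", "IMF"):
        bv_scaled[t] = bv[t] * np.sqrt(h2[t]) * _TRAIT_SCALE[t][1]
    bv_scaled["RFI"] = g_rfi

    truth = PhenoTruth(
        snp_effects=effects,
        breeding_values=bv_scaled,
        batch_effects=pd.DataFrame(batch_effects, index=range(1, cfg.batch_count + 1)),
        age_slope=age_slopes,
    )
    return pheno, truth


# --------------------------------------------------------------------------
# expression

def simulate_expression(
    G: GenotypeMatrix,
    ann: SnpAnnotation,
    groups: pd.Series,
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExprTruth]:
    """Simulate a log2 muscle expression matrix for the individuals in ``groups``.

    ``groups`` maps individual ids (a subset of ``G.ids``) to ``"HFE"``,
    ``"LFE"`` or ``"none"``. Expression = gene baseline + batch effect +
    laboratory effect + cis eSNP effect (SNP within 1 Mb of the gene) +
    trans eSNP effects + ``de_effect`` added to ``n_de_genes`` genes for LFE
    individuals + Gaussian noise. Per-gene/sample detection flags mimic an
    array detection call: a minority of dim genes falls below threshold.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 37])
    unknown = [i for i in groups.index if i not in set(G.ids)]
    if unknown:
        raise ValueError(f"groups reference unknown individuals: {unknown[:5]}")
    samples = list(groups.index)
    Gs = G.subset_individuals(samples)
    n = len(samples)

    genes = ann.genes["gene"].to_numpy()
    if len(genes) < cfg.n_genes_expressed:
        raise ValueError("annotation has fewer genes than n_genes_expressed")
    expressed = rng.choice(genes, size=cfg.n_genes_expressed, replace=False)
    gene_info = ann.genes.set_index("gene").loc[expressed]

    dim = rng.random(cfg.n_genes_expressed) < 0.15
    baseline = np.where(
        dim,
        rng.normal(3.5, 0.8, size=cfg.n_genes_expressed),
        rng.normal(7.0, 1.5, size=cfg.n_genes_expressed),
    )

    # sample factors: batches inherited from genotype order hash-free; lab split ~66:38
    batch = rng.integers(1, cfg.batch_count + 1, size=n)
    n_lab1 = int(round(n * 66.0 / 104.0))
    lab = np.array([1] * n_lab1 + [2] * (n - n_lab1))
    rng.shuffle(lab)

    vals = np.tile(baseline[:, None], (1, n))
    batch_eff = rng.normal(0.0, 0.2, size=(cfg.n_genes_expressed, cfg.batch_count))
    vals += batch_eff[:, batch - 1]
    lab_eff = rng.normal(cfg.lab_effect_mean, cfg.lab_effect_sd,
                         size=cfg.n_genes_expressed)
    vals += lab_eff[:, None] * (lab == 2)[None, :]

    dosage = np.nan_to_num(Gs.dosage())
    meta = Gs.snp_meta.set_index("snp")

    # cis eQTL: pick genes with a SNP within 1 Mb of the gene body
    cis_rows, trans_rows = [], []
    candidates = rng.permutation(cfg.n_genes_expressed)
    snp_by_chrom = {c: sub for c, sub in Gs.snp_meta.groupby("chrom")}
    n_cis = 0
    for gi in candidates:
        if n_cis >= cfg.n_cis_eqtl:
            break
        info = gene_info.iloc[gi]
        sub = snp_by_chrom.get(info["chrom"])
        if sub is None:
            continue
        near = sub[(sub["pos"] >= info["start"] - 1_000_000)
                   & (sub["pos"] <= info["end"] + 1_000_000)]
        near = near[(meta.loc[near["snp"], "maf"] > 0.1).to_numpy()]
        if near.empty:
            continue
        snp = near["snp"].iloc[int(rng.integers(0, len(near)))]
        j = Gs.snp_meta.index[Gs.snp_meta["snp"] == snp][0]
        vals[gi] += cfg.eqtl_effect * dosage[:, j]
        cis_rows.append((expressed[gi], snp, cfg.eqtl_effect))
        n_cis += 1
    used = {r[0] for r in cis_rows}
    for gi in candidates:
        if len(trans_rows) >= cfg.n_trans_eqtl:
            break
        if expressed[gi] in used:
            continue
        info = gene_info.iloc[gi]
        far = Gs.snp_meta[Gs.snp_meta["chrom"] != info["chrom"]]
        if far.empty:
            continue
        j = int(rng.integers(0, len(far)))
        snp = far["snp"].iloc[j]
        vals[gi] += cfg.eqtl_effect * dosage[:, far.index[j]]
        trans_rows.append((expressed[gi], snp, cfg.eqtl_effect))
        used.add(expressed[gi])

    # group-wise DE: higher expression in the low-feed-efficiency group
    de_pool = [g for k, g in enumerate(expressed) if not dim[k]]
    n_de = min(cfg.n_de_genes, len(de_pool))
    de_genes = list(rng.choice(de_pool, size=n_de, replace=False)) if n_de else []
    lfe = (groups.to_numpy() == "LFE")
    gene_pos = {g: k for k, g in enumerate(expressed)}
    for g in de_genes:
        vals[gene_pos[g]] += cfg.de_effect * lfe

    vals += rng.normal(0.0, cfg.expr_noise_sd, size=vals.shape)
    detection = vals > 4.5

    values = pd.DataFrame(vals, index=expressed, columns=samples)
    det = pd.DataFrame(detection, index=expressed, columns=samples)
    sample_meta = pd.DataFrame(
        {"batch": batch, "laboratory": lab, "group": groups.to_numpy()}, index=samples
    )
    truth = ExprTruth(
        cis_eqtl=pd.DataFrame(cis_rows, columns=["gene", "snp", "effect"]),
        trans_eqtl=pd.DataFrame(trans_rows, columns=["gene", "snp", "effect"]),
        de_genes=de_genes,
        lab_effects=pd.Series(lab_eff, index=expressed),
    )
    return ExpressionMatrix(values, sample_meta, det), truth
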