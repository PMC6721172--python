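# Methods

This note documents the models implemented in `fenet`, the synthetic data
they are exercised on, and the numerical and design choices that were
genuinely open.

## Synthetic population (`fenet.simdata`)

The generator emulates a paternal half-sib feed-efficiency design: by
default 350 offspring of 5 sires, each offspring with its own unrelated dam,
distributed over 4 fattening batches in a partially balanced connected
layout (one batch holds all families; each later batch omits one family,
cyclically). Age at the trial midpoint is uniform on [121, 148] days, with
slaughter ~55 days later.

**Genotypes.** SNPs are laid out on 18 autosomes with 5–60 kb spacing.
Founder haplotypes are assembled per LD block (default 10 SNPs) from a
shared haplotype pool whose size scales with the founder count
(`max(16, n_founders/4)`); gametes copy one parental haplotype per block.
This produces within-block LD, Mendelian-consistent offspring and the
half-sib relationship contrast (within-family minus between-family genomic
relationship ≈ 0.25) without a coalescent simulator. It does not produce a
realistic decay of LD with distance, mutation, or selection — tests passing
on these data say nothing about those features of real genotypes. Because
only 5 sires contribute half of all offspring alleles, observed offspring
allele frequencies drift substantially around their founder targets; this
is a property of the real design too.

**Phenotypes.** Seven production traits (ADG, BW, BF, CW, KO, LEAN, IMF)
follow `y = μ + batch + slope·(age − 135) + g + e` at the trait scales of
the study population (e.g. ADG 0.89 ± 0.11 kg/d, BF 24 ± 4.9 mm).
The genetic value `g` combines `qtl_per_trait` QTL (default 50) holding 60%
of the genetic variance with a polygenic background over all SNPs, and is
standardized in-sample so realized heritabilities (default 0.3–0.5 per
trait) hit their targets exactly. Pleiotropy: within designated trait
groups ({ADG, BW, CW} and {BF, IMF} by default) a configurable fraction of
QTL is shared with identical effects (effect correlation 1) — the simplest
architecture that yields the observed trait-cluster structure. Feed intake
is *assembled*, not drawn: `ADFI = μ + batch + α·age + γ_(j)·MW + δ1_(j)·ADG
+ δ2_(j)·BF + RFI_true`, with batch-varying nested coefficients and a
heritable residual-intake component (SD 0.17 kg/d, h² = 0.5), so that RFI
and FCR are recovered by the trait-derivation stage exactly as in the real
analysis rather than simulated directly. True per-SNP effects and breeding
values are stored for recovery tests.

**Expression.** Log2 expression = gene baseline (N(7, 1.5²); a 15% "dim"
fraction at N(3.5, 0.8²) exercises the detection filter) + per-gene batch
effects + a laboratory shift for lab-2 samples (66:38 split) + cis eSNP
effects (SNP within 1 Mb of the gene, 1.0 log2/allele by default) + trans
effects + a group shift (`de_effect`) added to `n_de_genes` genes in the
low-feed-efficiency animals + N(0, 0.5²) noise. Detection flags threshold
the simulated intensity at 4.5. Probe-level artifacts (cross-hybridization,
probe GC effects) are not modelled; the preprocessing stage treats each
simulated gene as a single probe.

## Trait derivation (`fenet.pheno`)

RFI is the residual of an ordinary least-squares fit of ADFI on batch
intercepts, one global age-midpoint covariate, and MW, ADG and BF each
nested within batch (the age covariate is read as un-nested; the nested
reading applies to the production covariates). Residuals are exactly
orthogonal to every design column, hence mean-zero and uncorrelated with
ADG within batch. QC order is fixed — missingness > 10%, then MAF < 5%
(strict inequalities: a SNP at exactly 0.05 survives), then a 1-df
chi-square Hardy–Weinberg test at p < 0.001 (an exact enumeration test is
available by flag), then unmapped/X — and remaining missing genotypes are
imputed to the rounded per-SNP mean dosage, which preserves allele
frequencies for relationship matrices. FCR with non-positive gain raises
rather than producing NaN.

## Mixed-model scans (`fenet.gwas`)

The GRM is either per-SNP-standardized, `G_ij = (1/m) Σ_k (x_ik − 2p_k)
(x_jk − 2p_k) / 2p_k(1−p_k)`, or the cross-product of centered genotypes
over `Σ 2p_k(1−p_k)`; the two correlate > 0.99 on these data. Allele
frequencies are estimated from the sample, so off-diagonals are shifted
down slightly (their mean is constrained near −1/n); the within- vs
between-family *contrast* is the stable quantity.

Variance components come from REML on the null model via the spectral
decomposition of K: data are rotated by the eigenvectors and the restricted
likelihood is optimized in the log variance ratio (grid + bounded Brent).
Boundary solutions are flagged; K proportional to the identity triggers a
non-identifiability warning. Each SNP is then tested by GLS with
`V = Kσ²u + Iσ²e` held fixed (two-step scan); the candidate SNP stays in
the GRM (no leave-one-chromosome-out), giving a small, documented
deflation. The residual variance factor in the SE makes the σ²u = 0 limit
collapse *exactly* onto per-SNP OLS. Tests are two-sided Wald with normal
p = 2(1 − Φ(|z|)). eGWAS adds a laboratory fixed effect, controls
multiplicity per gene across SNPs (BH; a Bonferroni column is also
reported), and labels an association cis when the SNP is within 1 Mb of the
gene start (inclusive; the start-vs-midpoint choice is a config option).

## AWM and PCIT (`fenet.awm`)

A SNP enters the AWM iff (p_key < 0.05) OR (≥ 3 other traits at p < 0.05),
AND it lies ≤ 10 kb from its nearest annotated gene; its row holds signed
z-scores for all nine traits. Trait structure: Pearson correlations of AWM
columns, complete-linkage clustering on 1 − r, Newick export. Row-profile
correlations rest on only 9 points; the module warns that their sampling
significance is not tested — PCIT replaces that test.

PCIT: for every trio the three first-order partials are computed
(`r_xy.z = (r_xy − r_xz r_yz)/√((1−r²_xz)(1−r²_yz))`), the tolerance is the
mean ratio of partial to raw correlation, and edge x–y is flagged when
|r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|. Aggregation is a config switch:
`any` (default — one flagging trio discards the edge) or `all`; both modes
are verified against a naive triple-loop reference. Degenerate trios
(|r| < 1e-12 in a tolerance denominator) contribute nothing, and partial
denominators are floored at 1e-24 before the square root. Edge weights are
the raw correlations; degree/hub logic uses connection counts only.

## Lossless regulator search (`fenet.regulators`)

Every trio/quartet of TF nodes is scored exhaustively with uint64 bitsets:
coverage is the open-neighborhood union *excluding the seed TFs themselves*
(a flag switches to inclusion; both modes are oracle-tested), redundancy is
the summed pairwise neighborhood overlap. Ranking: coverage descending,
redundancy ascending, lexicographic. Because members are excluded, the best
quartet can cover one node fewer than the best trio when the fourth TF adds
no new neighbors — visible in small networks. A 10⁷-combination guard
instructs the caller to pre-filter TFs by degree.

## Transcriptome stages (`fenet.expr`)

**Moderated DE.** Per-gene least squares of log2 expression on group +
batch + laboratory. Residual variances are shrunk toward an
intensity-dependent prior: the log-variances (bias-corrected via digamma)
are lowess-smoothed on mean intensity, the prior df d₀ is obtained by
matching the residual spread to trigamma(d_g/2) + trigamma(d₀/2) (inverse
trigamma by bracketed root-finding), and the moderated t uses
`(d₀s₀² + d_g s²_g)/(d₀ + d_g)` with d_g + d₀ degrees of freedom. d₀ = 0
reproduces the ordinary t exactly. Fold change: Δ is the adjusted log2
difference LFE − HFE; the reported FC is `sign(Δ)·2^|Δ|` and the |FC| > 1.5
threshold is applied on the linear scale (a log-scale flag exists) — the
linear scale is the only reading consistent with fold changes near 5 for
top genes on log2 data.

**sPLS-DA.** NIPALS with the X-weight vector soft-thresholded to exactly
keepX nonzero entries per component, regression-mode deflation, and
max-distance class prediction through the regression coefficients
`W(PᵀW)⁻¹Cᵀ`. Tuning minimizes repeated stratified k-fold BER; tuning
repetitions default to 50 in the API (500 reproduces the original protocol;
the desk-scale pipeline uses 10). The first component is oriented so HFE
samples score positive; genes elevated in LFE therefore load negative.

**rCCA.** Canonical directions from the eigen-decomposition of
`(S_XX + λ₁I)⁻¹ S_XY (S_YY + λ₂I)⁻¹ S_YX` on standardized blocks. With λ's
unset, each side's shrinkage intensity is the analytic
`Σ Var̂(r_ij) / Σ r²_ij` estimator clipped to [0, 1]; the original study's
printed λ's are accepted directly for replication and are the pipeline
defaults. Gene "loadings" are structure correlations with the gene-side
canonical variate (stable signs, unlike raw ridge weights); CC1 is oriented
so the key trait (RFI) carries a negative weight, making the two methods'
loadings sign-concordant. Gene retention: among the CC1-weighted population
(|loading| above its median; `all` is an option — the defining population
of the rule is ambiguous in the source protocol), genes whose maximum
absolute trait correlation exceeds median + 2·SD of that distribution.

**Integration.** Candidates are genes reported by ≥ 2 of {DE, sPLS-DA,
rCCA}; concordance is the Pearson correlation of first-component loadings
over genes selected by both multivariate methods.

## Genomic prediction (`fenet.predict`)

The pedigree A matrix uses the tabular method (founders non-inbred).
The animal model `y = Xb + u + e`, `u ~ N(0, Rσ²u)` is Gibbs-sampled with
flat priors on locations and scaled inverse chi-square conditionals with
ν = −2 (flat on variances). With one record per individual the conditional
precision of u diagonalizes in the eigenbasis of R, so every update is
elementwise and 20k-iteration chains take about a second for n = 350.
Defaults follow the original protocol (100,000 iterations, 10,000 burn-in,
thin 10); the desk-scale preset uses 20,000/2,000/10. A split-chain
potential-scale-reduction heuristic on h² (> 1.1) is recorded as a warning,
never raised. Zero eigenvalues pin the corresponding rotated effects to
zero; near-singular matrices get a flagged 1e-6 ridge.

GBLUP solves the mixed-model equations with training records only;
validation animals receive fixed effects plus breeding values propagated
through R. Cross-validation: 20 random ~88/12 splits, resampled (up to 100
attempts, logged) if a validation batch level is missing from training;
accuracy is the Pearson correlation of predicted and observed phenotypes.
Variance components are estimated once on the full data, exactly as in the
original protocol — this carries an optimistic bias for panels selected on
the same data, which is the point being reproduced, and is why the
AWM-panel accuracy on synthetic data (~0.65) should not be read as
out-of-sample accuracy. Since every simulated animal is genotyped,
single-step blending reduces to plain GBLUP; H-matrix construction is out
of scope.

## Problem sizes

The test suite and the acceptance script run everything at desk scale as
the package's own default study conditions: 350 animals × 5,000 SNPs for
population-level experiments, 1,200 SNPs for heritability recovery, 1,500
simulated genes (1,000 for DE calibration), 20k-iteration Gibbs chains,
20-seed/20-replicate Monte-Carlo summaries. Full-array scale (30K+ SNPs)
runs through the same code paths via configuration.

## Known limitations

- With only 5 half-sib families, h² under the *pedigree* matrix is weakly
  identified: flat-prior posterior means are biased toward the prior mass
  (measured ≈ +0.07 at truth 0.5). The heritability-recovery experiment
  therefore uses the genomic relationship matrix, where the posterior mean
  is unbiased to within ±0.05; the pedigree case is asserted only at the
  per-simulation ±0.15 band.
- FCR, a ratio of two noisy traits, occasionally drives the REML variance
  ratio to its boundary on synthetic data; the fit flags this rather than
  failing.
- PCIT on a full 30K-SNP AWM row set is O(n³) per aggregation pass; the
  desk-scale AWM (~100 rows) is instantaneous, and a few hundred rows take
  seconds. Very large networks would need chunked trio evaluation.
- The sPLS-DA BER on strongly separated synthetic groups is often exactly
  0; permuted labels recover chance (≈ 0.5), which is the calibration that
  matters.
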