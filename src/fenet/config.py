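"""Pipeline configuration with the study's analysis settings as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

#: every numeric analysis default, with the design fact it encodes
DEFAULTS: list[tuple[str, object, str]] = [
    ("qc_maf_min", 0.05, "SNPs with minor allele frequency below 5% are removed"),
    ("qc_miss_max", 0.10, "SNPs with more than 10% missing genotypes are removed"),
    ("qc_hwe_p", 0.001, "Hardy-Weinberg departure threshold p = 0.001"),
    ("awm_key_trait", "RFI", "residual feed intake is the key (target) phenotype"),
    ("awm_p_thresh", 0.05, "nominal association threshold for AWM retention"),
    ("awm_min_other", 3, "or associated with at least 3 of the other 8 traits"),
    ("awm_max_dist", 10_000, "retained SNPs lie within 10 kb of the nearest gene"),
    ("pcit_aggregation", "any", "an edge is discarded as soon as one trio flags it"),
    ("de_fc_thresh", 1.5, "differential expression requires |fold change| > 1.5"),
    ("de_q_thresh", 0.05, "and a false-discovery-rate q-value below 0.05"),
    ("splsda_ncomp", 2, "two sparse PLS-DA components"),
    ("splsda_folds", 5, "five-fold cross-validation"),
    ("splsda_reps", 500, "repeated 500 times"),
    ("rcca_lambda1", 0.121138, "trait-side shrinkage regularization"),
    ("rcca_lambda2", 0.128887, "gene-side shrinkage regularization"),
    ("rcca_select_sd", 2.0, "gene retained when max |trait correlation| > median + 2 SD"),
    ("egwas_q_thresh", 0.05, "genome-wide eSNP significance at q <= 0.05"),
    ("egwas_cis_window", 1_000_000, "cis when SNP and gene positions differ by <= 1 Mb"),
    ("gibbs_iters", 100_000, "Gibbs chain length"),
    ("gibbs_burnin", 10_000, "burn-in rounds"),
    ("gibbs_thin", 10, "one sample kept out of each 10"),
    ("cv_replicates", 20, "random cross-validation replicates"),
    ("cv_train_frac", 0.88, "approximately 88% of records train, 12% validate"),
    ("n_extreme_per_group", 10, "10 high- and 10 low-feed-efficiency pigs for DE"),
    ("n_expression_samples", 104, "muscle expression profiled on 104 pigs"),
]

_DEFAULT_MAP = {name: value for name, value, _ in DEFAULTS}


@dataclass
class PipelineConfig:
    # synthetic-population settings (see fenet.simdata.SimConfig)
    sim: dict = field(default_factory=dict)
    seed: int = 0
    # stage toggles
    run_expression: bool = True
    run_egwas: bool = True
    run_prediction: bool = True
    # genotype QC
    qc_maf_min: float = _DEFAULT_MAP["qc_maf_min"]
    qc_miss_max: float = _DEFAULT_MAP["qc_miss_max"]
    qc_hwe_p: float = _DEFAULT_MAP["qc_hwe_p"]
    # AWM selection and network
    awm_key_trait: str = _DEFAULT_MAP["awm_key_trait"]
    awm_p_thresh: float = _DEFAULT_MAP["awm_p_thresh"]
    awm_min_other: int = _DEFAULT_MAP["awm_min_other"]
    awm_max_dist: int = _DEFAULT_MAP["awm_max_dist"]
    pcit_aggregation: str = _DEFAULT_MAP["pcit_aggregation"]
    # differential expression
    de_fc_thresh: float = _DEFAULT_MAP["de_fc_thresh"]
    de_q_thresh: float = _DEFAULT_MAP["de_q_thresh"]
    # multivariate analyses
    splsda_ncomp: int = _DEFAULT_MAP["splsda_ncomp"]
    splsda_folds: int = _DEFAULT_MAP["splsda_folds"]
    splsda_reps: int = _DEFAULT_MAP["splsda_reps"]
    splsda_keepX: list[int] | None = None
    rcca_lambda1: float = _DEFAULT_MAP["rcca_lambda1"]
    rcca_lambda2: float = _DEFAULT_MAP["rcca_lambda2"]
    rcca_select_sd: float = _DEFAULT_MAP["rcca_select_sd"]
    # eGWAS
    egwas_q_thresh: float = _DEFAULT_MAP["egwas_q_thresh"]
    egwas_cis_window: int = _DEFAULT_MAP["egwas_cis_window"]
    egwas_max_genes: int = 40
    # prediction
    gibbs_iters: int = _DEFAULT_MAP["gibbs_iters"]
    gibbs_burnin: int = _DEFAULT_MAP["gibbs_burnin"]
    gibbs_thin: int = _DEFAULT_MAP["gibbs_thin"]
    cv_replicates: int = _DEFAULT_MAP["cv_replicates"]
    cv_train_frac: float = _DEFAULT_MAP["cv_train_frac"]
    # expression sampling
    n_extreme_per_group: int = _DEFAULT_MAP["n_extreme_per_group"]
    n_expression_samples: int = _DEFAULT_MAP["n_expression_samples"]

    def __post_init__(self) -> None:
        if self.pcit_aggregation not in ("any", "all"):
            raise ValueError("pcit_aggregation must be 'any' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def desk_scale(self) -> "PipelineConfig":
        """A reduced preset that runs the full pipeline in minutes."""
        import dataclasses

        return dataclasses.replace(
            self,
            sim={"n_individuals": 350, "n_snps": 5000, "n_genes_expressed": 1500,
                 **self.sim},
            splsda_reps=10,
            splsda_keepX=self.splsda_keepX or [50, 50],
            gibbs_iters=20_000,
            gibbs_burnin=2_000,
        )
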