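"""Configuration objects for the simulator and the pipeline orchestrator."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic case/control study generator.

    The defaults emulate the shape of a mid-sized case/control GWAS with a
    right-skewed gene-length distribution (so the min-p gene-size bias exists
    before correction), pathway collections with planted jointly-associated
    gene sets, prior scores correlated with the planted genes, and a
    scale-free directed interaction network containing every gene.

    Parameters
    ----------
    n_cases, n_controls
        Sample sizes of the two phenotype groups.
    n_genes
        Number of protein-coding gene models to generate.
    gene_length_log_mean, gene_length_log_sd
        Parameters of the log-normal gene-length law (base-pair scale).
        ``exp(10) ~ 22 kb`` median matches a typical gene-length skew.
    snp_density_per_bp
        Expected SNPs per base pair of the flank-extended gene region; the
        per-gene SNP count is Poisson in the region length (min 1), which
        makes SNP count grow with gene length.
    max_snps_per_gene
        Hard cap on the per-gene SNP count.
    maf_range
        Minor-allele-frequency interval, within (0, 0.5].
    n_pathways
        Number of gene sets in the synthetic collection.
    pathway_size_log_mean, pathway_size_log_sd
        Log-normal integer law for pathway sizes, truncated to
        ``[pathway_min_size, pathway_max_size]``.
    pathway_min_size, pathway_max_size
        Bounds of the truncated pathway-size law.
    n_planted_pathways
        Number of pathways enriched for causal genes.
    per_snp_odds_ratio
        Allelic odds ratio of every causal SNP (>0; 1.0 means null).
    frac_causal_genes_per_planted_pathway
        Proportion of each planted pathway's members that are causal.
    prior_score_shape, prior_score_scale
        Gamma law of the background combined score CS (support >= 0).
    prior_score_causal_shift
        Additive shift of CS for causal genes (mean separation delta).
    network_nodes
        Node count of the directed interaction network (>= n_genes; extra
        nodes model network objects without a measured gene).
    network_attachment
        Out-edges attached per incoming node during preferential attachment.
    inhibition_fraction
        Proportion of edges labelled ``inhibition`` (rest ``activation``).
    within_gene_corr
        Optional exchangeable correlation of genotypes within a gene
        (default 0: SNPs independent, no linkage disequilibrium).
    missing_rate
        Proportion of genotype entries masked as missing (default 0).
    genes_per_chromosome
        Genes tiled per synthetic chromosome, non-overlapping with flanks.
    rng_seed
        Master seed; identical config + seed give identical outputs.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_genes: int = 1000
    gene_length_log_mean: float = 10.0
    gene_length_log_sd: float = 1.0
    snp_density_per_bp: float = 1.0 / 8000.0
    max_snps_per_gene: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_pathways: int = 60
    pathway_size_log_mean: float = 3.0
    pathway_size_log_sd: float = 0.5
    pathway_min_size: int = 10
    pathway_max_size: int = 100
    n_planted_pathways: int = 5
    per_snp_odds_ratio: float = 1.3
    frac_causal_genes_per_planted_pathway: float = 0.5
    prior_score_shape: float = 2.0
    prior_score_scale: float = 0.5
    prior_score_causal_shift: float = 2.0
    network_nodes: int = 1200
    network_attachment: int = 2
    inhibition_fraction: float = 0.2
    within_gene_corr: float = 0.0
    missing_rate: float = 0.0
    genes_per_chromosome: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_pathways",
                     "network_nodes", "genes_per_chromosome",
                     "max_snps_per_gene"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.per_snp_odds_ratio <= 0:
            raise ConfigurationError("per_snp_odds_ratio must be > 0")
        if not (0.0 < self.frac_causal_genes_per_planted_pathway <= 1.0):
            raise ConfigurationError(
                "frac_causal_genes_per_planted_pathway must be in (0, 1]")
        if self.n_planted_pathways < 0 or self.n_planted_pathways > self.n_pathways:
            raise ConfigurationError("planted pathways must be <= total pathways")
        if not (0.0 <= self.inhibition_fraction <= 1.0):
            raise ConfigurationError("inhibition_fraction must be in [0, 1]")
        if self.network_attachment < 1:
            raise ConfigurationError("network_attachment must be >= 1")
        if self.network_nodes < self.n_genes:
            raise ConfigurationError("network_nodes must cover all genes")
        if not (0.0 <= self.within_gene_corr < 1.0):
            raise ConfigurationError("within_gene_corr must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.pathway_min_size > self.pathway_max_size:
            raise ConfigurationError("pathway size bounds inverted")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class RunConfig:
    """Pipeline orchestration: input paths, analysis constants, seeds.

    Round-trips losslessly through YAML so a run is fully described by one
    file plus the input data.
    """

    # inputs
    genotypes: str = ""
    genotype_dialect: str = "ped_map"  # or "tsv"
    gene_models: str = ""
    pathways: str = ""
    prior_scores: str = ""
    network: str = ""
    out_dir: str = "results"

    # analysis constants
    flank_bp: int = 20000
    lambda_mode: str = "auto"          # "auto" or a number as string
    lambda_grid_step: float = 0.01
    lambda_permutations: int = 20
    n_permutations: int = 5000
    permutation_scheme: str = "phenotype"  # or "gene"
    pathway_min_size: int = 10
    pathway_max_size: int = 380
    gene_sig_threshold: float = 0.05
    fdr_q: float = 0.05
    weighting: str = "weighted"        # "weighted", "equal" or "both"
    seed_p_cutoff: float = 0.05
    cs_cutoff_mode: str = "mean"       # "mean" or "median"
    subnetwork_node_limit: int = 50

    # seeds per stage
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gene_sig_threshold", "fdr_q", "seed_p_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        for name in ("flank_bp",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("lambda_permutations", "n_permutations",
                     "subnetwork_node_limit", "pathway_min_size",
                     "pathway_max_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.permutation_scheme not in ("phenotype", "gene"):
            raise ConfigurationError("permutation_scheme must be phenotype|gene")
        if self.weighting not in ("weighted", "equal", "both"):
            raise ConfigurationError("weighting must be weighted|equal|both")
        if self.cs_cutoff_mode not in ("mean", "median"):
            raise ConfigurationError("cs_cutoff_mode must be mean|median")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
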