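"""Synthetic case/control study generator.

Produces every pipeline input with the statistical structure the analysis
assumes: a right-skewed (log-normal) gene-length distribution whose per-gene
SNP count grows with length (so the min-p gene-size bias exists before
correction), Hardy-Weinberg genotypes with configurable minor-allele
frequencies, pathway collections with planted jointly-associated gene sets,
prior combined scores shifted upward for causal genes, and a scale-free
directed interaction network labelled with activation/inhibition effects.

Causal SNPs shift the case allele frequency to match a chosen allelic odds
ratio: with control minor-allele frequency ``p0`` and odds ratio ``OR``,

    p1 = OR * p0 / (1 - p0 + OR * p0),

the 2x2 allele-table odds identity. SNPs are simulated independently within
and between genes — no linkage disequilibrium — so the effective number of
tests per gene equals the SNP count and the tuned correction exponent sits
near 1 (full Sidak); an exchangeable within-gene correlation knob exists
but is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from gwaspathnet.config import SimulationConfig, ConfigurationError
from gwaspathnet.study import GenotypeStudy, PathwayCollection, MISSING

FLANK_BP = 20_000
_GENE_GAP_BP = 41_000       # > 2 flanks: neighbouring flank regions disjoint
_CHROM_OFFSET_BP = 25_000   # first gene starts clear of coordinate zero
_MIN_GENE_BP = 200


@dataclass
class GroundTruth:
    """What the generator planted, for power/recall evaluation."""

    causal_snp_ids: set = field(default_factory=set)
    causal_gene_ids: set = field(default_factory=set)
    planted_pathway_ids: set = field(default_factory=set)
    seed_used: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "causal_snp_ids": sorted(self.causal_snp_ids),
            "causal_gene_ids": sorted(self.causal_gene_ids),
            "planted_pathway_ids": sorted(self.planted_pathway_ids),
            "seed_used": self.seed_used,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(set(d["causal_snp_ids"]), set(d["causal_gene_ids"]),
                   set(d["planted_pathway_ids"]), d["seed_used"])


def _rngs(config: SimulationConfig, n: int = 6):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.rng_seed).spawn(n)]


def gen_gene_models(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models tiling synthetic chromosomes, plus the SNP map.

    Gene lengths are log-normal; genes tile non-overlapping intervals
    (flank regions disjoint too) with ``genes_per_chromosome`` genes per
    chromosome. The per-gene SNP count is Poisson in the gene length
    (minimum 1, capped), so it correlates positively with length; SNP
    positions are uniform over the gene interval extended by 20 kb flanks.

    Returns ``(gene_models, snp_map)``: BED-convention gene intervals
    (0-based half-open) and 1-based SNP positions with the generating gene.
    """
    if rng is None:
        rng = _rngs(config)[0]
    lengths = np.maximum(
        _MIN_GENE_BP,
        np.round(rng.lognormal(config.gene_length_log_mean,
                               config.gene_length_log_sd,
                               config.n_genes))).astype(np.int64)
    n_snps = rng.poisson(lengths * config.snp_density_per_bp)
    n_snps = np.clip(n_snps, 1, config.max_snps_per_gene)

    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    chroms, starts, ends = [], [], []
    cursor, chrom_no, on_chrom = _CHROM_OFFSET_BP, 1, 0
    for L in lengths:
        if on_chrom == config.genes_per_chromosome:
            chrom_no += 1
            on_chrom = 0
            cursor = _CHROM_OFFSET_BP
        chroms.append(f"chr{chrom_no}")
        starts.append(cursor)
        ends.append(cursor + int(L))
        cursor += int(L) + _GENE_GAP_BP
        on_chrom += 1
    gene_models = pd.DataFrame({
        "gene_id": gene_ids, "chrom": chroms,
        "start": np.array(starts, dtype=np.int64),
        "end": np.array(ends, dtype=np.int64),
    })
    gene_models["length"] = gene_models["end"] - gene_models["start"]

    rows = []
    for g, chrom, s, e, k in zip(gene_ids, chroms, starts, ends, n_snps):
        lo, hi = s - FLANK_BP, e + FLANK_BP  # 0-based half-open region
        pos0 = rng.choice(hi - lo, size=int(k), replace=False) + lo
        for p0 in np.sort(pos0):
            rows.append((chrom, int(p0) + 1, g))  # 1-based SNP position
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id"])
    snp_map = snp_map.sort_values(["chrom", "pos"],
                                  key=lambda s: (s.str.removeprefix("chr")
                                                 .astype(int)
                                                 if s.name == "chrom" else s)
                                  ).reset_index(drop=True)
    snp_map.insert(0, "snp_id",
                   [f"rs{i:07d}" for i in range(1, len(snp_map) + 1)])
    return gene_models, snp_map


def case_allele_frequency(p0: np.ndarray, odds_ratio: float) -> np.ndarray:
    """Case minor-allele frequency matching an allelic odds ratio."""
    if odds_ratio <= 0:
        raise ConfigurationError("odds ratio must be > 0")
    p0 = np.asarray(p0, dtype=float)
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def gen_genotypes(config: SimulationConfig, snp_map: pd.DataFrame,
                  causal_gene_ids=frozenset(),
                  rng: np.random.Generator | None = None
                  ) -> tuple[GenotypeStudy, GroundTruth]:
    """HWE genotypes; causal SNPs get odds-ratio-shifted case frequencies.

    Non-causal SNPs draw minor-allele counts Binomial(2, MAF) identically
    in cases and controls with MAF ~ Uniform(maf_range). SNPs inside causal
    genes use the shifted case frequency. Sample columns are cases first.
    """
    if snp_map.empty:
        raise ValueError("SNP map is empty")
    if rng is None:
        rng = _rngs(config)[1]
    n_snps = len(snp_map)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, n_snps)
    causal = snp_map["gene_id"].isin(set(causal_gene_ids)).to_numpy()
    p_case = np.where(
        causal, case_allele_frequency(maf, config.per_snp_odds_ratio), maf)

    g_case = rng.binomial(2, p_case[:, None],
                          (n_snps, config.n_cases)).astype(np.int8)
    g_ctrl = rng.binomial(2, maf[:, None],
                          (n_snps, config.n_controls)).astype(np.int8)

    if config.within_gene_corr > 0:
        # exchangeable within-gene correlation: per sample, copy the gene's
        # first SNP with probability `within_gene_corr`
        for mat in (g_case, g_ctrl):
            first = snp_map.groupby("gene_id", sort=False).head(1).index
            tmpl = pd.Series(first,
                             index=snp_map.loc[first, "gene_id"]).to_dict()
            copy = rng.random(mat.shape) < config.within_gene_corr
            for i, gid in enumerate(snp_map["gene_id"]):
                t = tmpl[gid]
                if t != i:
                    mat[i, copy[i]] = mat[t, copy[i]]

    genotypes = np.concatenate([g_case, g_ctrl], axis=1)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    sample_ids = ([f"case{i:05d}" for i in range(1, config.n_cases + 1)] +
                  [f"ctrl{i:05d}" for i in range(1, config.n_controls + 1)])
    is_case = np.r_[np.ones(config.n_cases, bool),
                    np.zeros(config.n_controls, bool)]
    study = GenotypeStudy(snp_map[["snp_id", "chrom", "pos"]].copy(),
                          genotypes, sample_ids, is_case)
    truth = GroundTruth(
        causal_snp_ids=set(snp_map.loc[causal, "snp_id"]),
        causal_gene_ids=set(causal_gene_ids),
        seed_used=config.rng_seed)
    return study, truth


def gen_pathways(config: SimulationConfig, gene_ids,
                 rng: np.random.Generator | None = None
                 ) -> tuple[PathwayCollection, GroundTruth]:
    """Pathway collection with planted causal-enriched gene sets.

    Sizes follow a truncated log-normal integer law. The first
    ``n_planted_pathways`` pathways are planted: an exact
    ``round(frac * size)`` of their members are causal genes (drawn
    disjointly across planted pathways while the universe allows); the
    remaining pathways sample their members uniformly from the full
    universe, so they contain causal genes only by chance.
    """
    if rng is None:
        rng = _rngs(config)[2]
    gene_ids = list(gene_ids)
    sizes = np.clip(
        np.round(rng.lognormal(config.pathway_size_log_mean,
                               config.pathway_size_log_sd,
                               config.n_pathways)).astype(int),
        config.pathway_min_size, config.pathway_max_size)
    if sizes.max(initial=0) > len(gene_ids):
        raise ConfigurationError("pathway size exceeds the gene universe")

    width = max(4, len(str(config.n_pathways)))
    pids = [f"PW{i:0{width}d}" for i in range(1, config.n_pathways + 1)]
    planted = set(pids[:config.n_planted_pathways])
    frac = config.frac_causal_genes_per_planted_pathway

    members: dict[str, tuple[str, ...]] = {}
    causal_pool: set[str] = set()
    available = list(gene_ids)
    for pid, size in zip(pids, sizes):
        if pid in planted:
            n_causal = int(round(frac * size))
            fresh = [g for g in available if g not in causal_pool]
            if len(fresh) >= n_causal:
                chosen = list(rng.choice(fresh, n_causal, replace=False))
            else:  # small universe: re-use causal genes across pathways
                chosen = list(rng.choice(sorted(causal_pool) + fresh,
                                         n_causal, replace=False))
            causal_pool.update(chosen)
            rest_pool = [g for g in gene_ids
                         if g not in causal_pool and g not in chosen]
            rest = list(rng.choice(rest_pool, size - n_causal, replace=False))
            members[pid] = tuple(sorted(chosen + rest))
        else:
            members[pid] = tuple(sorted(rng.choice(gene_ids, size,
                                                   replace=False)))
    collection = PathwayCollection(
        members,
        descriptions={p: ("planted" if p in planted else "background")
                      for p in pids},
        source={p: "synthetic" for p in pids})
    truth = GroundTruth(causal_gene_ids=causal_pool,
                        planted_pathway_ids=planted,
                        seed_used=config.rng_seed)
    return collection, truth


def gen_prior_scores(config: SimulationConfig, gene_ids,
                     causal_gene_ids=frozenset(),
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Combined prior scores: Gamma background, causal genes shifted up.

    ``CS = Gamma(shape, scale)`` for every gene, plus
    ``prior_score_causal_shift`` for causal genes, so the group-mean
    difference equals the shift in expectation and all scores are >= 0.
    """
    if rng is None:
        rng = _rngs(config)[3]
    gene_ids = list(gene_ids)
    cs = rng.gamma(config.prior_score_shape, config.prior_score_scale,
                   len(gene_ids))
    causal = np.isin(np.asarray(gene_ids, dtype=object),
                     np.asarray(sorted(causal_gene_ids), dtype=object))
    cs = cs + np.where(causal, config.prior_score_causal_shift, 0.0)
    return pd.DataFrame({"gene_id": gene_ids, "CS": cs})


def gen_network(config: SimulationConfig, gene_ids,
                rng: np.random.Generator | None = None) -> nx.DiGraph:
    """Scale-free-ish directed network containing every gene as a node.

    Nodes arrive in random order; each attaches ``network_attachment``
    edges to distinct existing nodes chosen with probability proportional
    to degree + 1, each edge independently oriented toward or away from
    the newcomer. Edges carry an ``effect`` label, ``inhibition`` with the
    configured fraction, ``activation`` otherwise. No self-loops, no
    parallel edges.
    """
    if rng is None:
        rng = _rngs(config)[4]
    gene_ids = list(gene_ids)
    n_extra = config.network_nodes - len(gene_ids)
    width = max(4, len(str(max(1, n_extra))))
    nodes = gene_ids + [f"OBJ{i:0{width}d}" for i in range(1, n_extra + 1)]
    order = list(rng.permutation(nodes))
    m = config.network_attachment

    G = nx.DiGraph()
    G.add_nodes_from(nodes)
    degree = {n: 0 for n in nodes}

    def effect():
        return ("inhibition" if rng.random() < config.inhibition_fraction
                else "activation")

    existing: list[str] = []
    for node in order:
        if existing:
            k = min(m, len(existing))
            wts = np.array([degree[v] + 1.0 for v in existing])
            targets = rng.choice(existing, size=k, replace=False,
                                 p=wts / wts.sum())
            for t in targets:
                u, v = (node, t) if rng.random() < 0.5 else (t, node)
                if not G.has_edge(u, v):
                    G.add_edge(u, v, effect=effect())
                    degree[u] += 1
                    degree[v] += 1
        existing.append(node)
    return G


@dataclass
class SimulatedStudy:
    """Bundle of all generated inputs plus the ground truth."""

    config: SimulationConfig
    gene_models: pd.DataFrame
    snp_map: pd.DataFrame
    study: GenotypeStudy
    pathways: PathwayCollection
    prior_scores: pd.DataFrame
    network: nx.DiGraph
    truth: GroundTruth


def simulate(config: SimulationConfig,
             out_dir: str | Path | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study (optionally written to disk).

    Pathways are generated before genotypes so the planted causal genes —
    always a subset of the planted pathways' members — can drive the
    odds-ratio shift of their SNPs. With ``out_dir`` set, writes PLINK
    .ped/.map, BED gene models, a GMT collection, the prior-score TSV, the
    edge TSV and the ground-truth JSON (byte-identical given the same
    config and seed).
    """
    r_genes, r_geno, r_path, r_prior, r_net, _ = _rngs(config)
    gene_models, snp_map = gen_gene_models(config, r_genes)
    pathways, truth = gen_pathways(config, gene_models["gene_id"], r_path)
    if config.per_snp_odds_ratio == 1.0:
        causal_genes: set[str] = set()
    else:
        causal_genes = truth.causal_gene_ids
    study, geno_truth = gen_genotypes(config, snp_map, causal_genes, r_geno)
    truth.causal_snp_ids = geno_truth.causal_snp_ids
    truth.causal_gene_ids = causal_genes
    prior = gen_prior_scores(config, gene_models["gene_id"],
                             truth.causal_gene_ids, r_prior)
    network = gen_network(config, gene_models["gene_id"], r_net)
    bundle = SimulatedStudy(config, gene_models, snp_map, study, pathways,
                            prior, network, truth)
    if out_dir is not None:
        from gwaspathnet import io
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_ped_map(study, out / "study.ped", out / "study.map")
        io.write_bed(gene_models, out / "genes.bed")
        io.write_gmt(pathways, out / "pathways.gmt")
        io.write_prior_tsv(prior, out / "prior_scores.tsv")
        io.write_edge_tsv(network, out / "network.tsv")
        truth.to_json(out / "ground_truth.json")
    return bundle
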