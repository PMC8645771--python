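"""Seed-based subnetwork expansion over a directed interaction network.

Seed genes (associated *and* prior-supported) are grown into subnetworks by
capped flow propagation: every seed carries a flow of 1; a node with flow
``f`` and ``d`` edges in the active direction sends ``f/d`` along each such
edge, and a receiving node accumulates the sum of its incoming flows,
truncated at 1. Growth repeatedly admits the highest-flow candidate (ties:
higher total degree, then lexicographic id), re-propagates, and stops at a
node limit; an outgoing and an ingoing phase are merged into one
subnetwork. Grown subnetworks are deleted from the working network and the
process repeats until the seed pool is exhausted.

Each subnetwork is ranked by its saturation with seed nodes: with ``r``
seeds among its ``n`` members, ``R`` seed objects in the network of ``N``
nodes, the Z-score standardises ``r`` by the exact hypergeometric moments

    Z = (r - n R/N) / sqrt( n (R/N) (1 - R/N) (N - n)/(N - 1) ),

and an upper-tail hypergeometric p-value accompanies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from gwaspathnet.config import ConfigurationError
from gwaspathnet.enrichment import bh_fdr


@dataclass
class SeedSet:
    """Genes passing both the association and the prior-score criterion."""

    seed_genes: tuple[str, ...]
    p_cutoff: float
    cs_mode: str
    cs_cutoff: float
    length_correlation: float | None = None
    length_correlation_p: float | None = None


def select_seeds(gene_scores: pd.DataFrame, prior_table: pd.DataFrame,
                 p_cutoff: float = 0.05, cs_mode: str = "mean",
                 gene_lengths: pd.Series | None = None) -> SeedSet:
    """Seeds: ``p_adj < p_cutoff`` and combined score above its central value.

    The central value is the mean of the combined scores over all scored
    genes (``cs_mode="median"`` selects the median instead); both
    inequalities are strict. When ``gene_lengths`` is given (indexed by
    gene id), the Pearson correlation between the selection indicator and
    gene length is reported as a large-gene-bias diagnostic.
    """
    if gene_scores.empty or prior_table.empty:
        raise ValueError("gene scores and prior table must be nonempty")
    if cs_mode not in ("mean", "median"):
        raise ConfigurationError("cs_mode must be mean|median")
    cs = prior_table.set_index("gene_id")["CS"].astype(float)
    cutoff = float(cs.mean() if cs_mode == "mean" else cs.median())
    t = gene_scores.set_index("gene_id")
    cs_al = cs.reindex(t.index)
    selected = (t["p_adj"] < p_cutoff) & (cs_al > cutoff)
    seeds = tuple(sorted(t.index[selected.fillna(False)]))
    if not seeds:
        raise ValueError(
            f"no seed genes: {int((t['p_adj'] < p_cutoff).sum())} pass "
            f"p_adj < {p_cutoff}, CS cutoff ({cs_mode}) = {cutoff:.4g}")
    corr = corr_p = None
    if gene_lengths is not None:
        lengths = gene_lengths.reindex(t.index).astype(float)
        ok = lengths.notna()
        if ok.sum() >= 3 and selected[ok].nunique() > 1:
            r = stats.pearsonr(selected[ok].astype(float), lengths[ok])
            corr, corr_p = float(r.statistic), float(r.pvalue)
    return SeedSet(seeds, p_cutoff, cs_mode, cutoff, corr, corr_p)


def propagate_flow(network: nx.DiGraph, sources: dict,
                   direction: str = "outgoing") -> tuple[dict, list]:
    """One propagation step: split each source's flow over its edges.

    ``sources`` maps node -> flow value in [0, 1]. A source with flow ``f``
    and ``d`` edges in the chosen direction sends ``f/d`` along each; every
    receiving node accumulates the sum of its incoming contributions,
    capped at 1. ``direction="ingoing"`` operates on the reversed graph.
    Returns ``(received, dead_ends)`` where ``dead_ends`` lists sources
    with no edge in the chosen direction.
    """
    if direction not in ("outgoing", "ingoing"):
        raise ConfigurationError("direction must be outgoing|ingoing")
    missing = [s for s in sources if s not in network]
    if missing:
        raise ValueError(f"source not in network: {missing[0]}")
    received: dict = {}
    dead: list = []
    for src, f in sources.items():
        nbrs = (list(network.successors(src)) if direction == "outgoing"
                else list(network.predecessors(src)))
        if not nbrs:
            dead.append(src)
            continue
        share = f / len(nbrs)
        for v in nbrs:
            received[v] = received.get(v, 0.0) + share
    for v in received:
        received[v] = min(received[v], 1.0)
    return received, dead


@dataclass
class Subnetwork:
    """A grown node set with its seed saturation statistics."""

    members: tuple[str, ...]
    seeds: tuple[str, ...]
    edges: list[tuple[str, str, str]]
    flows: dict = field(default_factory=dict)
    zscore: float = float("nan")
    p_hyper: float = float("nan")
    singleton: bool = False
    annotations: pd.DataFrame | None = None

    @property
    def n_node(self) -> int:
        return len(self.members)

    @property
    def r_node(self) -> int:
        return len(self.seeds)

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "seeds": list(self.seeds),
            "edges": [list(e) for e in self.edges],
            "n_node": self.n_node,
            "r_node": self.r_node,
            "zscore": None if np.isnan(self.zscore) else self.zscore,
            "p_hyper": None if np.isnan(self.p_hyper) else self.p_hyper,
            "singleton": self.singleton,
        }


def _tie_key(network: nx.DiGraph):
    def key(item):
        node, flow = item
        return (-flow, -network.degree(node), node)
    return key


def _admission_phase(network: nx.DiGraph, seeds, node_limit: int,
                     direction: str) -> tuple[set, dict]:
    """Grow one direction: admit highest-flow candidates one at a time.

    Members start as the seeds with flow 1; after each admission the flows
    are recomputed from the enlarged member set (admitted nodes forward
    their received flow rather than re-emitting 1).
    """
    members = {s: 1.0 for s in seeds}
    admitted: dict = {}
    while len(admitted) < node_limit:
        received, _dead = propagate_flow(network, members, direction)
        candidates = {v: f for v, f in received.items() if v not in members}
        if not candidates:
            break
        best, flow = min(candidates.items(), key=_tie_key(network))
        admitted[best] = flow
        members[best] = flow
    return set(admitted), admitted


def grow_subnetwork(network: nx.DiGraph, seeds, node_limit: int = 50,
                    flows_out: dict | None = None) -> Subnetwork:
    """Grow one connected subnetwork from the given seeds.

    Flow admission runs over an outgoing and an ingoing phase (at most
    ``node_limit`` admissions each) starting from every seed present in the
    network. The returned subnetwork is the weakly connected component of
    the grown node set that contains the highest-degree seed (ties broken
    lexicographically); its member seeds are the contributing seeds. If
    that seed reaches no neighbour, the result is a flagged singleton.
    """
    present = sorted(s for s in seeds if s in network)
    if not present:
        raise ValueError("no seed remains in the working network")
    out_nodes, out_flows = _admission_phase(network, present, node_limit,
                                            "outgoing")
    in_nodes, in_flows = _admission_phase(network, present, node_limit,
                                          "ingoing")
    all_nodes = set(present) | out_nodes | in_nodes
    sub = network.subgraph(all_nodes)
    comps = list(nx.weakly_connected_components(sub))
    anchor = min(present, key=lambda s: (-network.degree(s), s))
    comp = next(c for c in comps if anchor in c)
    members = tuple(sorted(comp))
    member_seeds = tuple(s for s in present if s in comp)
    edges = [(u, v, d.get("effect", "unspecified"))
             for u, v, d in network.subgraph(comp).edges(data=True)]
    flows = {n: max(out_flows.get(n, 0.0), in_flows.get(n, 0.0))
             for n in members if n not in present}
    return Subnetwork(members, member_seeds, sorted(edges), flows,
                      singleton=(len(members) == 1))


def decompose(network: nx.DiGraph, seed_set: SeedSet | tuple,
              node_limit: int = 50) -> list[Subnetwork]:
    """Cut the network into subnetworks by repeated growth and deletion.

    Each grown subnetwork's members are deleted from the working network
    and its seeds from the seed pool, until no mapped seed remains. Every
    seed therefore appears in at most one subnetwork. Output is sorted by
    saturation Z-score descending (undefined Z last, then by id).
    """
    seeds = (seed_set.seed_genes if isinstance(seed_set, SeedSet)
             else tuple(seed_set))
    if not seeds:
        raise ValueError("seed set is empty")
    N_node = network.number_of_nodes()
    if N_node == 0:
        raise ValueError("network is empty")
    mapped = [s for s in seeds if s in network]
    R_object = len(mapped)
    working = network.copy()
    remaining = set(mapped)
    subnets: list[Subnetwork] = []
    while remaining:
        sn = grow_subnetwork(working, sorted(remaining), node_limit)
        sn.zscore = saturation_zscore(sn.r_node, sn.n_node, R_object, N_node)
        sn.p_hyper = subnetwork_pvalue(sn.r_node, sn.n_node, R_object, N_node)
        subnets.append(sn)
        working.remove_nodes_from(sn.members)
        remaining -= set(sn.members)
    subnets.sort(key=lambda s: (np.isnan(s.zscore), -(s.zscore if not
                 np.isnan(s.zscore) else 0.0), s.members))
    return subnets


def saturation_zscore(r_node: int, n_node: int, R_object: int,
                      N_node: int) -> float:
    """Standardised seed saturation under hypergeometric sampling.

    ``Z = (r - n R/N) / SD`` with the exact hypergeometric standard
    deviation ``SD = sqrt(n (R/N)(1 - R/N)(N - n)/(N - 1))`` — the moments
    of drawing ``n`` of ``N`` network nodes containing ``R`` seed objects.
    Returns NaN when the variance is zero (R = 0, R = N or n = N).
    """
    _check_counts(r_node, n_node, R_object, N_node)
    R, N, n, r = float(R_object), float(N_node), float(n_node), float(r_node)
    var = n * (R / N) * (1 - R / N) * (N - n) / (N - 1)
    if var <= 0:
        return float("nan")
    return (r - n * R / N) / np.sqrt(var)


def subnetwork_pvalue(r_node: int, n_node: int, R_object: int,
                      N_node: int) -> float:
    """Upper-tail hypergeometric p: P(X >= r) for X ~ Hypergeom(N, R, n)."""
    _check_counts(r_node, n_node, R_object, N_node)
    return float(stats.hypergeom.sf(r_node - 1, N_node, R_object, n_node))


def _check_counts(r_node, n_node, R_object, N_node):
    if N_node < 2:
        raise ValueError("network must have at least 2 nodes")
    if not (0 < n_node <= N_node):
        raise ValueError("0 < n_node <= N_node required")
    if not (0 <= R_object <= N_node):
        raise ValueError("0 <= R_object <= N_node required")
    if not (0 <= r_node <= min(n_node, R_object)):
        raise ValueError("0 <= r_node <= min(n_node, R_object) required")


def annotate_subnetwork(subnetwork: Subnetwork, collection,
                        universe) -> pd.DataFrame:
    """Gene-set over-representation among a subnetwork's member genes.

    For each gene set, the hypergeometric upper-tail p of the overlap with
    the subnetwork's members (within the universe) and the member-coverage
    percentage are reported, BH-adjusted across sets.
    """
    universe = set(universe)
    members = set(subnetwork.members) & universe
    table = collection.universe_members or collection.members
    rows = []
    for pid, genes in table.items():
        gs = set(genes) & universe
        k = len(gs & members)
        frac = 100.0 * k / len(members) if members else 0.0
        p = (float(stats.hypergeom.sf(k - 1, len(universe), len(gs),
                                      len(members)))
             if members and gs else 1.0)
        rows.append({"set_id": pid, "n_overlap": k,
                     "member_fraction_pct": frac, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        _, out["p_BH"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "set_id"]).reset_index(drop=True)
    subnetwork.annotations = out
    return out
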