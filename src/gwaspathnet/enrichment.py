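"""Pathway enrichment: weighted GSEA, weighted sum-statistic, hypergeometric test.

Genes enter ranked by a weighted statistic ``w_j * r_j`` where
``r_j = -ln(p_adj_j)`` is the gene-wise significance and
``w_j = 1 + CS_j / mean(CS)`` up-weights genes with prior-knowledge
combined scores (``w = 1`` for unscored genes, so every weight is >= 1).

Three tests are offered:

* **wGSEA** (competitive): a running sum walks the ranked genome, gaining
  ``|w r|^p / N_R`` at member genes (``N_R`` the total member gain) and
  losing ``1 / (N - N_H)`` elsewhere; the enrichment score ES is the
  maximum prefix sum, normalised to NES against permutation nulls.
* **wSS** (self-contained): the sum of member ``w r`` values, with a
  permutation p-value.
* **hypergeometric** (competitive, unweighted): over-representation of
  significant genes (``p_adj < 0.05``) in the pathway.

Empirical p-values use the add-one convention ``(1 + #{null > obs}) / (B + 1)``
so no pathway reports p = 0; Benjamini-Hochberg step-up controls the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gwaspathnet.config import ConfigurationError
from gwaspathnet.study import GenotypeStudy, PathwayCollection
from gwaspathnet.gene_scores import (
    GeneSnpAssignment, allelic_test_matrix, _minp_only, fosco_adjust,
)

#: floor applied to p_adj = 0 before taking the log
P_FLOOR = 1e-300


def compute_weights(prior_table: pd.DataFrame, gene_universe,
                    equal_weight: bool = False) -> pd.DataFrame:
    """Per-gene weights ``w = 1 + CS / mean(CS)`` over the gene universe.

    ``prior_table`` has columns gene_id, CS (CS >= 0). The mean is taken
    over the genes that carry a prior score; genes absent from the table
    get ``w = 1``. ``equal_weight=True`` sets every weight to 1 (the
    unweighted analysis). Returns a frame gene_id, CS, w covering the
    universe, with the mean score in ``.attrs["CS_bar"]``.
    """
    universe = list(gene_universe)
    cs = prior_table.set_index("gene_id")["CS"].astype(float)
    if (cs < 0).any():
        raise ValueError("combined scores must be non-negative")
    scored = cs.reindex(universe).dropna()
    out = pd.DataFrame({"gene_id": universe})
    out["CS"] = cs.reindex(universe).to_numpy()
    if equal_weight:
        out["w"] = 1.0
        out.attrs["CS_bar"] = float(scored.mean()) if len(scored) else np.nan
        return out
    if len(scored) == 0 or scored.mean() == 0:
        raise ValueError(
            "all combined scores are zero; weighting is undefined — "
            "use equal_weight=True")
    cs_bar = float(scored.mean())
    w = 1.0 + out["CS"].fillna(0.0) / cs_bar
    out["w"] = w.to_numpy()
    out.attrs["CS_bar"] = cs_bar
    return out


def gene_statistic(gene_scores: pd.DataFrame,
                   weights: pd.DataFrame | None = None,
                   eps: float = P_FLOOR) -> pd.DataFrame:
    """Ranked weighted gene statistics ``r = -ln(p_adj)``, ``wr = w * r``.

    ``gene_scores`` needs columns gene_id, p_adj. Zero p-values are floored
    at ``eps`` and flagged. The returned frame is sorted by ``wr``
    descending with ties broken by gene_id, which makes the ranking total.
    """
    t = gene_scores[["gene_id", "p_adj"]].copy()
    floored = t["p_adj"].to_numpy() <= 0.0
    p = np.clip(t["p_adj"].to_numpy(dtype=float), eps, 1.0)
    t["r"] = -np.log(p)
    t["floored"] = floored
    if weights is not None:
        wmap = weights.set_index("gene_id")["w"]
        t["w"] = wmap.reindex(t["gene_id"]).fillna(1.0).to_numpy()
    else:
        t["w"] = 1.0
    t["wr"] = t["w"] * t["r"]
    t = t.sort_values(["wr", "gene_id"], ascending=[False, True],
                      kind="mergesort").reset_index(drop=True)
    return t


def filter_pathways(collection: PathwayCollection, universe,
                    min_size: int = 10, max_size: int = 380) -> PathwayCollection:
    """Intersect memberships with the universe and drop extreme sizes.

    A pathway is kept iff its universe-intersected size lies in the closed
    interval ``[min_size, max_size]``; both the raw and intersected
    memberships are retained on the result.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    kept = PathwayCollection({}, {}, {}, {})
    for pid, genes in collection.members.items():
        inter = tuple(sorted(set(genes) & universe))
        if min_size <= len(inter) <= max_size:
            kept.members[pid] = genes
            kept.universe_members[pid] = inter
            if pid in collection.descriptions:
                kept.descriptions[pid] = collection.descriptions[pid]
            if pid in collection.source:
                kept.source[pid] = collection.source[pid]
    return kept


def _es_from_mask(wr_ranked: np.ndarray, member_mask: np.ndarray,
                  exponent_p: float = 1.0) -> tuple[float, bool]:
    """ES of one pathway given the ranked statistics and a member mask."""
    N = wr_ranked.size
    NH = int(member_mask.sum())
    if not (0 < NH < N):
        raise ValueError("pathway must be a proper nonempty subset of the universe")
    gains = np.abs(wr_ranked) ** exponent_p
    NR = float(gains[member_mask].sum())
    if NR == 0.0:
        return 0.0, True
    step = np.where(member_mask, gains / NR, -1.0 / (N - NH))
    return float(step.cumsum().max()), False


def enrichment_score(ranked: pd.DataFrame, pathway_genes,
                     exponent_p: float = 1.0) -> float:
    """Running-sum enrichment score of a pathway on the ranked gene list.

    ``ranked`` is the output of :func:`gene_statistic` (sorted by ``wr``
    descending). Member genes contribute ``|wr|^p / N_R``; non-members
    subtract ``1/(N - N_H)``; the ES is the maximum prefix sum. Scaling all
    statistics by a positive constant leaves the ES unchanged (the
    normaliser cancels when ``p = 1``).
    """
    member_mask = ranked["gene_id"].isin(set(pathway_genes)).to_numpy()
    es, _flagged = _es_from_mask(ranked["wr"].to_numpy(), member_mask, exponent_p)
    return es


def sum_statistic(ranked: pd.DataFrame, pathway_genes) -> float:
    """Self-contained sum of the weighted statistics over member genes."""
    mask = ranked["gene_id"].isin(set(pathway_genes)).to_numpy()
    if not mask.any():
        raise ValueError("pathway has no gene in the universe")
    return float(ranked.loc[mask, "wr"].sum())


def observed_scores(ranked: pd.DataFrame, collection: PathwayCollection,
                    exponent_p: float = 1.0) -> pd.DataFrame:
    """ES and SS of every (filtered) pathway on the observed ranking."""
    rows = []
    for pid, genes in collection.universe_members.items():
        rows.append({
            "pathway_id": pid,
            "ES": enrichment_score(ranked, genes, exponent_p),
            "SS": sum_statistic(ranked, genes),
            "n_universe": len(genes),
            "n_raw": len(collection.members[pid]),
        })
    return pd.DataFrame(rows)


def permutation_null(collection: PathwayCollection, B: int, seed: int,
                     scheme: str = "gene", *,
                     ranked: pd.DataFrame | None = None,
                     study: GenotypeStudy | None = None,
                     assignment: GeneSnpAssignment | None = None,
                     lam: float | None = None,
                     weights: pd.DataFrame | None = None,
                     exponent_p: float = 1.0) -> dict:
    """Null ES and SS samples for every pathway in the collection.

    scheme="gene"
        Gene labels are permuted on the observed ranked statistics
        (``ranked`` required): each pathway's members become a uniformly
        random gene set of the same size, the statistics themselves fixed.
        Fast, and exact for a competitive null.
    scheme="phenotype"
        Case/control labels are permuted and the whole gene-score stage is
        recomputed per permutation (``study``, ``assignment``, ``lam`` and
        optionally ``weights`` required); the tuned ``lam`` and the weights
        are held fixed from the observed analysis.

    Returns ``{"pathway_ids": [...], "ES": (B, P) array, "SS": (B, P) array}``.
    """
    if B < 1:
        raise ConfigurationError("number of permutations B must be >= 1")
    pids = list(collection.universe_members)
    rng = np.random.default_rng(seed)
    es_null = np.empty((B, len(pids)))
    ss_null = np.empty((B, len(pids)))

    if scheme == "gene":
        if ranked is None:
            raise ValueError("scheme='gene' requires the observed ranked statistics")
        wr = ranked["wr"].to_numpy()
        N = wr.size
        gene_pos = {g: i for i, g in enumerate(ranked["gene_id"])}
        gains_all = np.abs(wr) ** exponent_p
        member_idx = {pid: np.array([gene_pos[g] for g in genes], dtype=np.int64)
                      for pid, genes in collection.universe_members.items()}
        perms = np.argsort(rng.random((B, N)), axis=1)
        for j, pid in enumerate(pids):
            pos = perms[:, member_idx[pid]]          # (B, NH) random positions
            NH = pos.shape[1]
            mask = np.zeros((B, N), dtype=bool)
            np.put_along_axis(mask, pos, True, axis=1)
            gains = np.where(mask, gains_all[None, :], 0.0)
            NR = gains.sum(axis=1, keepdims=True)
            safe_NR = np.where(NR == 0, 1.0, NR)
            step = np.where(mask, gains / safe_NR, -1.0 / (N - NH))
            es = step.cumsum(axis=1).max(axis=1)
            es_null[:, j] = np.where(NR.ravel() == 0, 0.0, es)
            ss_null[:, j] = np.where(mask, wr[None, :], 0.0).sum(axis=1)
    elif scheme == "phenotype":
        if study is None or assignment is None or lam is None:
            raise ValueError("scheme='phenotype' requires study, assignment and lam")
        w_map = None
        if weights is not None:
            w_map = weights.set_index("gene_id")["w"]
        n_samples = study.genotypes.shape[1]
        n_case = study.n_cases
        gene_ids = list(assignment.gene_ids)
        M = assignment.M
        w_vec = (w_map.reindex(gene_ids).fillna(1.0).to_numpy()
                 if w_map is not None else np.ones(len(gene_ids)))
        member_of = {pid: np.isin(np.asarray(gene_ids, dtype=object),
                                  np.asarray(genes, dtype=object))
                     for pid, genes in collection.universe_members.items()}
        gid_arr = np.asarray(gene_ids, dtype=object)
        for b in range(B):
            perm_case = np.zeros(n_samples, dtype=bool)
            perm_case[rng.choice(n_samples, size=n_case, replace=False)] = True
            res = allelic_test_matrix(study, is_case=perm_case)
            p_min = _minp_only(assignment, res["p"].to_numpy())
            p_adj = fosco_adjust(p_min, M, lam)
            r = -np.log(np.clip(p_adj, P_FLOOR, 1.0))
            wr = w_vec * r
            order = np.lexsort((gid_arr, -wr))
            wr_ranked = wr[order]
            for j, pid in enumerate(pids):
                mask = member_of[pid][order]
                es, _ = _es_from_mask(wr_ranked, mask, exponent_p)
                es_null[b, j] = es
                ss_null[b, j] = wr[member_of[pid]].sum()
    else:
        raise ConfigurationError(f"unknown permutation scheme: {scheme}")
    return {"pathway_ids": pids, "ES": es_null, "SS": ss_null}


def empirical_p_and_nes(observed: float, null_samples,
                        strict: bool = True) -> tuple[float, float]:
    """Add-one empirical p and the normalised score against the null sample.

    ``p = (1 + #{null > observed}) / (B + 1)`` (``>=`` with
    ``strict=False``); ``NES = (observed - mean(null)) / sd(null)``. A null
    sample with zero variance leaves NES undefined (NaN).
    """
    null_samples = np.asarray(null_samples, dtype=float)
    B = null_samples.size
    if B < 1:
        raise ValueError("need at least one null sample")
    exceed = (null_samples > observed) if strict else (null_samples >= observed)
    p = (1.0 + int(exceed.sum())) / (B + 1.0)
    sd = float(np.std(null_samples, ddof=1)) if B >= 2 else 0.0
    mean = float(null_samples.mean())
    # guard against a numerically-nonzero sd on a constant sample
    degenerate = sd <= 1e-12 * max(1.0, abs(mean))
    nes = (observed - mean) / sd if not degenerate else float("nan")
    return p, nes


def hypergeometric_test(universe_size: int, significant_count: int,
                        pathway_size: int, overlap: int) -> float:
    """Upper-tail over-representation p: P(X >= overlap).

    ``X`` is hypergeometric — draw ``pathway_size`` genes without
    replacement from a universe of ``universe_size`` containing
    ``significant_count`` significant genes.
    """
    N, K, n, k = universe_size, significant_count, pathway_size, overlap
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values, q_star: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection set and adjusted p-values.

    Rejects every hypothesis with rank up to the largest ``i`` such that
    ``p(i) <= (i/m) q_star``; adjusted p-values are the monotone step-up
    transform. Controls the FDR at ``q_star`` under independence.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p_values, alpha=q_star, method="fdr_bh")
    return reject, p_adj


_CROSSTALK_BINS = ("none", "<20%", "20-70%", ">70%")


def pathway_crosstalk(collection: PathwayCollection, gene_scores: pd.DataFrame,
                      sig_threshold: float = 0.05,
                      denominator: str = "smaller") -> pd.DataFrame:
    """Pairwise overlap of significant genes between pathways.

    For each pathway pair the count and proportion of shared significant
    genes (``p_adj < sig_threshold``) is reported and binned as
    none / <20% / 20-70% / >70%. The proportion's denominator is the
    significant-gene count of the smaller pathway by default
    (``denominator`` in {"smaller", "union", "jaccard"}).
    """
    if denominator not in ("smaller", "union", "jaccard"):
        raise ConfigurationError("denominator must be smaller|union|jaccard")
    sig = set(gene_scores.loc[gene_scores["p_adj"] < sig_threshold, "gene_id"])
    pids = list(collection.universe_members or collection.members)
    table = collection.universe_members or collection.members
    sig_members = {pid: set(table[pid]) & sig for pid in pids}
    rows = []
    for i, a in enumerate(pids):
        for b_ in pids[i + 1:]:
            sa, sb = sig_members[a], sig_members[b_]
            inter = sa & sb
            if denominator == "smaller":
                denom = min(len(sa), len(sb))
            elif denominator == "union":
                denom = len(sa | sb)
            else:
                denom = len(sa | sb)
            prop = len(inter) / denom if denom else 0.0
            if len(inter) == 0:
                bin_ = "none"
            elif prop < 0.2:
                bin_ = "<20%"
            elif prop <= 0.7:
                bin_ = "20-70%"
            else:
                bin_ = ">70%"
            rows.append({"pathway_a": a, "pathway_b": b_,
                         "n_overlap": len(inter), "proportion": prop,
                         "bin": bin_})
    return pd.DataFrame(rows)


def run_enrichment(gene_scores: pd.DataFrame, collection: PathwayCollection,
                   prior_table: pd.DataFrame | None, *,
                   methods=("gsea", "ss", "hyper"),
                   weighting: str = "weighted",
                   B: int = 5000, scheme: str = "gene", seed: int = 0,
                   sig_threshold: float = 0.05, q_star: float = 0.05,
                   study: GenotypeStudy | None = None,
                   assignment: GeneSnpAssignment | None = None,
                   lam: float | None = None,
                   exponent_p: float = 1.0) -> pd.DataFrame:
    """One enrichment pass: observed scores, permutation p, BH adjustment.

    Returns a long-format results frame with one row per
    (pathway, method, weighting); permutation-based methods carry ES/NES or
    SS with empirical p, the hypergeometric test carries its nominal p.
    BH adjustment is applied within each (method, weighting) column.
    """
    equal = weighting == "equal"
    if prior_table is not None and not equal:
        weights = compute_weights(prior_table, gene_scores["gene_id"])
    else:
        weights = compute_weights(
            prior_table if prior_table is not None
            else pd.DataFrame({"gene_id": [], "CS": []}),
            gene_scores["gene_id"], equal_weight=True)
    ranked = gene_statistic(gene_scores, weights)
    obs = observed_scores(ranked, collection, exponent_p)
    if obs.empty:
        return obs

    frames = []
    need_null = ("gsea" in methods) or ("ss" in methods)
    if need_null:
        null = permutation_null(
            collection, B, seed, scheme, ranked=ranked, study=study,
            assignment=assignment, lam=lam,
            weights=weights if scheme == "phenotype" else None,
            exponent_p=exponent_p)
        idx = {pid: j for j, pid in enumerate(null["pathway_ids"])}
    for method in methods:
        t = obs[["pathway_id", "n_universe", "n_raw"]].copy()
        t["method"] = {"gsea": "wGSEA" if not equal else "GSEA",
                       "ss": "wSS" if not equal else "SS",
                       "hyper": "hypergeometric"}[method]
        t["weighting"] = weighting
        if method == "gsea":
            stats_col, obs_col = "ES", obs["ES"].to_numpy()
            pe, nes = zip(*(empirical_p_and_nes(
                obs_col[i], null["ES"][:, idx[pid]])
                for i, pid in enumerate(obs["pathway_id"])))
            t["ES"], t["NES"], t["p_empirical"] = obs_col, nes, pe
        elif method == "ss":
            obs_col = obs["SS"].to_numpy()
            pe = [empirical_p_and_nes(obs_col[i], null["SS"][:, idx[pid]])[0]
                  for i, pid in enumerate(obs["pathway_id"])]
            t["SS"], t["p_empirical"] = obs_col, pe
        elif method == "hyper":
            universe = gene_scores["gene_id"]
            sig = set(gene_scores.loc[gene_scores["p_adj"] < sig_threshold,
                                      "gene_id"])
            N, K = len(universe), len(sig)
            pn = []
            for pid in obs["pathway_id"]:
                genes = set(collection.universe_members[pid])
                pn.append(hypergeometric_test(N, K, len(genes),
                                              len(genes & sig)))
            t["p_nominal"] = pn
        else:
            raise ConfigurationError(f"unknown method: {method}")
        pcol = "p_empirical" if method in ("gsea", "ss") else "p_nominal"
        _, t["p_BH"] = bh_fdr(t[pcol].to_numpy(), q_star)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
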