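"""Readers and writers for the plain-text interchange formats.

Coordinate conventions follow each format's own: BED gene intervals are
0-based half-open, .map and SNP positions are 1-based. All readers reject
malformed input with a located error rather than silently coercing, and
every write-then-read round-trips the in-memory records exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from gwaspathnet.study import GenotypeStudy, PathwayCollection, MISSING

_VALID_ALLELES = set("ACGT")
_MINOR, _MAJOR = "A", "G"  # synthetic allele coding used by the writer


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")


# ---------------------------------------------------------------- PLINK text

def write_ped_map(study: GenotypeStudy, ped_path, map_path) -> None:
    """PLINK text: .map (chrom, snp_id, 0, bp) and .ped (samples as rows).

    Minor-allele counts are encoded with alleles A (minor) / G (major);
    missing calls become the PLINK ``0 0`` code; phenotype is 2 for cases,
    1 for controls.
    """
    with open(map_path, "w") as fh:
        for _, row in study.snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    code = {0: f"{_MAJOR} {_MAJOR}", 1: f"{_MINOR} {_MAJOR}",
            2: f"{_MINOR} {_MINOR}", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for j, sid in enumerate(study.sample_ids):
            pheno = 2 if study.is_case[j] else 1
            geno = "\t".join(code[int(g)] for g in study.genotypes[:, j])
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{pheno}\t{geno}\n")


def read_ped_map(ped_path, map_path) -> GenotypeStudy:
    """Read PLINK text files into a study of minor-allele counts.

    The minor allele of each SNP is determined in the full sample (ties
    break to the lexicographically smaller allele); ``0`` is the missing
    code; phenotype 2 means case, anything else control.
    """
    snps = []
    seen = set()
    with open(map_path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(map_path, i, "expected 4 tab-separated fields")
            chrom, snp_id, _, bp = parts
            if snp_id in seen:
                raise ParseError(map_path, i, f"duplicate SNP id: {snp_id}")
            seen.add(snp_id)
            snps.append((snp_id, chrom, int(bp)))
    snp_table = pd.DataFrame(snps, columns=["snp_id", "chrom", "pos"])
    n_snps = len(snp_table)

    sample_ids, is_case, allele_rows = [], [], []
    with open(ped_path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6 + n_snps:
                raise ParseError(ped_path, i,
                                 f"expected {6 + n_snps} fields, got {len(parts)}")
            sample_ids.append(parts[1])
            is_case.append(parts[5] == "2")
            row = []
            for k, pair in enumerate(parts[6:]):
                alleles = pair.split(" ")
                if len(alleles) != 2:
                    raise ParseError(ped_path, i,
                                     f"genotype {k + 1} is not an allele pair")
                for a in alleles:
                    if a != "0" and a not in _VALID_ALLELES:
                        raise ParseError(ped_path, i,
                                         f"unknown allele symbol {a!r}")
                row.append(tuple(alleles))
            allele_rows.append(row)
    if not allele_rows:
        raise ParseError(ped_path, 0, "no samples")

    genotypes = np.full((n_snps, len(sample_ids)), MISSING, dtype=np.int8)
    for s in range(n_snps):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[s]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue  # all-missing SNP stays MISSING
        # minor allele: least frequent, ties to lexicographically smaller;
        # a monomorphic SNP's sole observed allele is treated as major
        if len(counts) == 1:
            minor = None
        else:
            minor = min(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        for j, row in enumerate(allele_rows):
            a1, a2 = row[s]
            if a1 == "0" or a2 == "0":
                continue
            genotypes[s, j] = (a1 == minor) + (a2 == minor)
    return GenotypeStudy(snp_table, genotypes, sample_ids,
                         np.asarray(is_case, dtype=bool))


# ------------------------------------------------------------- genotype TSV

def write_genotype_tsv(study: GenotypeStudy, path) -> None:
    """Genotype TSV dialect: ``#cases:`` header line, then a count matrix.

    Line 1 lists the case sample ids; line 2 is the column header
    (snp_id, chrom, pos, one column per sample); counts are 0/1/2 with NA
    for missing.
    """
    cases = [s for s, c in zip(study.sample_ids, study.is_case) if c]
    with open(path, "w") as fh:
        fh.write("#cases:" + ",".join(cases) + "\n")
        fh.write("\t".join(["snp_id", "chrom", "pos"] + study.sample_ids) + "\n")
        for i, (_, row) in enumerate(study.snps.iterrows()):
            vals = ["NA" if g == MISSING else str(int(g))
                    for g in study.genotypes[i]]
            fh.write("\t".join([row["snp_id"], str(row["chrom"]),
                                str(row["pos"])] + vals) + "\n")


def read_genotype_tsv(path) -> GenotypeStudy:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#cases:"):
            raise ParseError(path, 1, "missing '#cases:' header line")
        cases = set(first[len("#cases:"):].split(",")) - {""}
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["snp_id", "chrom", "pos"]:
            raise ParseError(path, 2, "bad column header")
        sample_ids = header[3:]
        snps, rows = [], []
        seen = set()
        for i, line in enumerate(fh, 3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(path, i, "ragged row")
            if parts[0] in seen:
                raise ParseError(path, i, f"duplicate SNP id: {parts[0]}")
            seen.add(parts[0])
            snps.append((parts[0], parts[1], int(parts[2])))
            try:
                rows.append([MISSING if v == "NA" else int(v)
                             for v in parts[3:]])
            except ValueError:
                raise ParseError(path, i, "non-integer genotype count")
    snp_table = pd.DataFrame(snps, columns=["snp_id", "chrom", "pos"])
    genotypes = np.asarray(rows, dtype=np.int8)
    is_case = np.array([s in cases for s in sample_ids])
    return GenotypeStudy(snp_table, genotypes, sample_ids, is_case)


# --------------------------------------------------------------------- BED

def write_bed(gene_models: pd.DataFrame, path) -> None:
    """4-column BED: chrom, start, end (0-based half-open), gene_id."""
    gene_models[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(path, i, "expected >= 4 BED fields")
            chrom, start, end, name = parts[:4]
            start, end = int(start), int(end)
            if end <= start:
                raise ParseError(path, i, f"malformed interval for {name}")
            rows.append((name, chrom, start, end))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    out["length"] = out["end"] - out["start"]
    return out


# --------------------------------------------------------------------- GMT

def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, genes in collection.members.items():
            desc = collection.descriptions.get(pid, "na")
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def read_gmt(path, source: str = "gmt") -> PathwayCollection:
    """GMT gene sets: pathway-id TAB description TAB gene...

    Duplicate member genes within a line are deduplicated with a warning;
    a line with fewer than 3 fields is a parse error.
    """
    members, descriptions, src = {}, {}, {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, "expected >= 3 tab-separated fields")
            pid, desc, genes = parts[0], parts[1], parts[2:]
            uniq = tuple(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"{path}:{i}: duplicate genes in {pid} "
                              "deduplicated")
            members[pid] = uniq
            descriptions[pid] = desc
            src[pid] = source
    if not members:
        warnings.warn(f"{path}: empty pathway collection")
    return PathwayCollection(members, descriptions, src)


# ---------------------------------------------------------- small TSV files

def write_prior_tsv(prior: pd.DataFrame, path) -> None:
    prior[["gene_id", "CS"]].to_csv(path, sep="\t", index=False)


def read_prior_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if list(t.columns[:2]) != ["gene_id", "CS"]:
        raise ParseError(path, 1, "expected columns gene_id, CS")
    if (t["CS"] < 0).any():
        bad = int(t.index[t["CS"] < 0][0]) + 2
        raise ParseError(path, bad, "negative combined score")
    return t


_EFFECTS = {"activation", "inhibition", "unspecified"}


def write_edge_tsv(network: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\teffect\n")
        for u, v, d in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('effect', 'unspecified')}\n")
    # isolated nodes are preserved via a commentless convention: none needed
    # for synthetic networks (attachment >= 1 connects every node)


def read_edge_tsv(path) -> nx.DiGraph:
    G = nx.DiGraph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "target", "effect"]:
            raise ParseError(path, 1, "expected header source/target/effect")
        for i, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(path, i, "expected 3 fields")
            u, v, eff = parts
            if u == v:
                raise ParseError(path, i, f"self-loop on {u}")
            if eff not in _EFFECTS:
                raise ParseError(path, i, f"unknown effect {eff!r}")
            G.add_edge(u, v, effect=eff)
    return G


def read_node_metadata(path) -> pd.DataFrame:
    """Optional node annotations: node_id, type, location[, gene]."""
    t = pd.read_csv(path, sep="\t")
    if "node_id" not in t.columns:
        raise ParseError(path, 1, "expected a node_id column")
    return t


# ------------------------------------------------------------------ results

def write_snp_results(results: pd.DataFrame, path) -> None:
    results[["snp_id", "chrom", "pos", "chi2", "p"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def write_gene_scores(table: pd.DataFrame, path) -> None:
    table[["gene_id", "M", "best_snp", "p_min", "M_eff", "p_adj"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_gene_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
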