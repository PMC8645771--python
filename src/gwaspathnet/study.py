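"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel in the minor-allele-count matrix


@dataclass
class GenotypeStudy:
    """A case/control study: SNP-by-sample minor-allele counts plus labels.

    ``genotypes`` holds minor-allele counts (0, 1, 2) with :data:`MISSING`
    (-1) for missing calls; rows follow ``snps`` (snp_id, chrom, pos),
    columns follow ``sample_ids``. ``is_case`` is a boolean vector aligned
    with the columns.
    """

    snps: pd.DataFrame              # columns: snp_id, chrom, pos (1-based)
    genotypes: np.ndarray           # int8, shape (n_snps, n_samples)
    sample_ids: list[str]
    is_case: np.ndarray             # bool, shape (n_samples,)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        n_snps, n_samples = self.genotypes.shape
        if len(self.snps) != n_snps:
            raise ValueError("snp table and genotype matrix disagree on SNP count")
        if len(self.sample_ids) != n_samples or len(self.is_case) != n_samples:
            raise ValueError("sample metadata and genotype matrix disagree")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup}")

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()


@dataclass
class PathwayCollection:
    """Gene sets with raw and universe-intersected sizes.

    ``members`` maps pathway id to the deduplicated member-gene tuple as
    read; ``universe_members`` (populated by filtering) maps to the members
    present in the analysed gene universe — the distinction between the
    number of genes in the pathway and the number measured on the chip.
    """

    members: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)
    universe_members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def sizes(self, universe: bool = False) -> pd.Series:
        table = self.universe_members if universe else self.members
        return pd.Series({k: len(v) for k, v in table.items()}, dtype=int)
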