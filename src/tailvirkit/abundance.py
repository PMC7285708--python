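"""Normalized coverage, relative abundance, and richness.

Normalized coverage of an entity (scaffold, gene, or vOTU) in a library is

    (mapped_nt / entity_length) / library_reads * mean(library_reads)

i.e. average per-base coverage rescaled to the mean library size across the
libraries present in the input. Relative abundance of a group of viral
entities in one sample is the group's summed normalized coverage divided by
the viral community total in that sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoverageMatrix:
    """Mapped-nucleotide counts (entities x libraries) plus lengths and reads."""
    mapped_nt: pd.DataFrame      # index entity_id, columns sample_id
    entity_length: pd.Series     # index entity_id
    reads: pd.Series             # index sample_id

    def __post_init__(self):
        self.entity_length = self.entity_length.reindex(self.mapped_nt.index)
        if self.entity_length.isna().any():
            missing = list(self.entity_length[self.entity_length.isna()].index[:5])
            raise ValueError(f"entities without length: {missing}")
        self.reads = self.reads.reindex(self.mapped_nt.columns)
        if self.reads.isna().any() or (self.reads <= 0).any():
            raise ValueError("every library needs a positive read count")
        if (self.entity_length <= 0).any():
            bad = list(self.entity_length[self.entity_length <= 0].index[:5])
            raise ValueError(f"zero-length entities: {bad}")
        if (self.mapped_nt.values < 0).any():
            raise ValueError("negative mapped_nt")

    @classmethod
    def from_long(cls, long_df: pd.DataFrame, lengths: pd.Series,
                  reads: pd.Series, entities: list[str] | None = None
                  ) -> "CoverageMatrix":
        wide = (long_df.pivot_table(index="entity_id", columns="sample_id",
                                    values="mapped_nt", aggfunc="sum", fill_value=0.0)
                .reindex(columns=list(reads.index), fill_value=0.0))
        if entities is not None:
            wide = wide.reindex(index=entities, fill_value=0.0)
        return cls(wide, lengths, reads)

    def subset(self, entity_ids: list[str]) -> "CoverageMatrix":
        return CoverageMatrix(self.mapped_nt.loc[entity_ids],
                              self.entity_length.loc[entity_ids], self.reads)

    def aggregate(self, partition: dict[str, str]) -> "CoverageMatrix":
        """Pool members into groups: summed mapped_nt over summed lengths.

        Coverage-weighted pooling — used to roll scaffolds up to vOTUs.
        """
        members = [e for e in self.mapped_nt.index if e in partition]
        labels = pd.Series({e: partition[e] for e in members})
        nt = self.mapped_nt.loc[members].groupby(labels).sum()
        ln = self.entity_length.loc[members].groupby(labels).sum()
        return CoverageMatrix(nt, ln, self.reads)


def normalized_coverage(m: CoverageMatrix) -> pd.DataFrame:
    """Entities x libraries normalized coverage (see module docstring)."""
    mean_reads = float(m.reads.mean())
    cov = m.mapped_nt.div(m.entity_length, axis=0)
    return cov.div(m.reads, axis=1) * mean_reads


def relative_abundance(group_ids, cov_norm: pd.DataFrame) -> pd.Series:
    """Per-sample relative abundance of a group within the whole matrix.

    Returns 0 where the group's sum is 0; NaN where the sample's community
    total is 0 (undefined).
    """
    if cov_norm.shape[0] == 0:
        return pd.Series(np.nan, index=cov_norm.columns)
    group_ids = list(group_ids)
    outside = set(group_ids) - set(cov_norm.index)
    if outside:
        raise ValueError(f"group ids outside the catalogue: {sorted(outside)[:5]}")
    total = cov_norm.sum(axis=0)
    grp = cov_norm.loc[group_ids].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = grp / total
    ra[(total == 0)] = np.nan
    ra[(grp == 0) & (total > 0)] = 0.0
    return ra


def richness(cov_norm: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Per-sample count of entities with normalized coverage > threshold."""
    return (cov_norm > threshold).sum(axis=0)
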