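"""Species-level vOTU clustering.

Greedy longest-first centroid clustering (UCLUST-style): sequences are sorted
by length descending (ties broken lexicographically by id), each unassigned
sequence seeds a vOTU, and every remaining unassigned sequence joins the seed
when its ANI to the seed is >= 95% and the alignment covers >= 85% of the
shorter sequence. The seed — the longest member — is the representative, so
membership conditions are checkable against the representative by
construction. A cheap prefilter skips pairs sharing fewer than 5 distinct
15-mers (treated as ANI 0); any true 95%-ANI pair shares orders of magnitude
more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp
from .alignment import PairwiseAlignmentStat, kmer_set, pairwise_ani
from .config import PipelineConfig


@dataclass
class VOTU:
    votu_id: str
    representative_id: str
    member_ids: list[str]
    taxonomy: str = ""
    member_stats: dict = field(default_factory=dict)  # member -> PairwiseAlignmentStat


def greedy_cluster(sequences, cfg: PipelineConfig | None = None,
                   taxonomy: dict[str, str] | None = None) -> list[VOTU]:
    """Partition sequences (objects with .id/.seq) into vOTUs.

    Output is invariant to input order: the length-descending sort makes the
    seed choice canonical.
    """
    cfg = cfg or PipelineConfig()
    taxonomy = taxonomy or {}
    seqs = sorted(sequences, key=lambda s: (-len(s.seq), s.id))
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("duplicate sequence ids")
    k = cfg.kmer_size
    ksets = {s.id: kmer_set(s.seq, k) | kmer_set(revcomp(s.seq), k) for s in seqs}

    unassigned = list(seqs)
    votus: list[VOTU] = []
    while unassigned:
        seed, rest = unassigned[0], unassigned[1:]
        members, stats, remaining = [seed.id], {}, []
        stats[seed.id] = PairwiseAlignmentStat(
            seed.id, seed.id, 1.0, 1.0, len(seed.seq), float(len(seed.seq)), "+")
        for s in rest:
            shared = len(ksets[seed.id] & ksets[s.id])
            if shared < cfg.prefilter_min_shared_kmers:
                remaining.append(s)
                continue
            st = pairwise_ani(seed, s, k=k)
            if st.ani >= cfg.ani_threshold and st.af_small >= cfg.af_threshold:
                members.append(s.id)
                stats[s.id] = st
            else:
                remaining.append(s)
        votus.append(VOTU(
            votu_id=f"vOTU_{len(votus) + 1:04d}",
            representative_id=seed.id,
            member_ids=members,
            taxonomy=taxonomy.get(seed.id, ""),
            member_stats=stats))
        unassigned = remaining
    return votus


def membership_table(votus: list[VOTU]) -> pd.DataFrame:
    rows = []
    for v in votus:
        for m in v.member_ids:
            st = v.member_stats[m]
            rows.append({"member_id": m, "votu_id": v.votu_id,
                         "representative_id": v.representative_id,
                         "ani_to_rep": round(st.ani, 4),
                         "af_to_rep": round(st.af_small, 4),
                         "taxonomy": v.taxonomy})
    return pd.DataFrame(rows, columns=["member_id", "votu_id", "representative_id",
                                       "ani_to_rep", "af_to_rep", "taxonomy"])


def partition_of(votus: list[VOTU]) -> dict[str, str]:
    return {m: v.votu_id for v in votus for m in v.member_ids}
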