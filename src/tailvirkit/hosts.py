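"""In-silico virus-host linking.

Three evidence types, each emitted as its own HostLink rows (reconciliation of
multi-evidence conflicts is left to the user):

* ``spacer`` — a CRISPR spacer recovered from a host scaffold occurs as an
  exact, full-length substring of a viral sequence on either strand (zero
  mismatches; N never matches).
* ``prophage`` — a curated prophage region sits on a scaffold belonging to a
  genome bin.
* ``shared_content`` — a merged alignment between virus and bin scaffold with
  aligned length >= 2.5 kb, identity >= 70%, and raw (+1/-2) score >= 50.

CRISPR arrays are detected as maximal runs of >= 3 exact direct repeats with
repeat length 23-47 nt and spacer length 20-50 nt; exact-repeat detection is
deliberately stricter than CRT-style fuzzy repeats, preserving the exact
spacer-matching contract downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp
from .alignment import kmer_set, pairwise_ani
from .config import PipelineConfig

log = logging.getLogger("tailvirkit.hosts")

REPEAT_LEN = (23, 47)
SPACER_LEN = (20, 50)
MIN_REPEATS = 3


@dataclass
class CrisprArray:
    host_scaffold_id: str
    repeat_consensus: str
    repeats: list[tuple[int, int]]            # (start, end) per repeat copy
    spacers: list[tuple[str, int, int]]       # (sequence, start, end)

    def __post_init__(self):
        if len(self.repeats) < MIN_REPEATS:
            raise ValueError("CRISPR array needs >= 3 repeats")

    @property
    def span(self) -> tuple[int, int]:
        return (self.repeats[0][0], self.repeats[-1][1])


@dataclass(frozen=True)
class HostLink:
    virus_id: str
    host_bin_id: str
    evidence: str           # spacer | prophage | shared_content
    detail: str
    unbinned: bool = False


# ---------------------------------------------------------------------------
# CRISPR detection
# ---------------------------------------------------------------------------

def detect_crispr(scaffold) -> list[CrisprArray]:
    """Find maximal exact direct-repeat arrays on one scaffold.

    For every repeat length L in [23, 47], occurrences of each repeated L-mer
    are chained when consecutive starts are separated by L + spacer with the
    spacer length in [20, 50]. Overlapping candidates are resolved by most
    repeats, then longest span, then leftmost start.
    """
    s = scaffold.seq
    candidates: list[tuple[int, int, int, str, list[int]]] = []
    for L in range(REPEAT_LEN[0], REPEAT_LEN[1] + 1):
        occ: dict[str, list[int]] = {}
        for i in range(len(s) - L + 1):
            occ.setdefault(s[i:i + L], []).append(i)
        gap_lo, gap_hi = L + SPACER_LEN[0], L + SPACER_LEN[1]
        for rep, positions in occ.items():
            if len(positions) < MIN_REPEATS or "N" in rep:
                continue
            run = [positions[0]]
            for p in positions[1:]:
                if gap_lo <= p - run[-1] <= gap_hi:
                    run.append(p)
                else:
                    if len(run) >= MIN_REPEATS:
                        candidates.append((len(run), run[-1] + L - run[0], -run[0], rep, run))
                    run = [p]
            if len(run) >= MIN_REPEATS:
                candidates.append((len(run), run[-1] + L - run[0], -run[0], rep, run))

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    chosen: list[CrisprArray] = []
    spans: list[tuple[int, int]] = []
    for _, _, _, rep, run in candidates:
        lo, hi = run[0], run[-1] + len(rep)
        if any(lo < h and l < hi for l, h in spans):
            continue
        spans.append((lo, hi))
        repeats = [(p, p + len(rep)) for p in run]
        spacers = [(s[repeats[i][1]:repeats[i + 1][0]], repeats[i][1], repeats[i + 1][0])
                   for i in range(len(repeats) - 1)]
        chosen.append(CrisprArray(scaffold.id, rep, repeats, spacers))
    chosen.sort(key=lambda a: a.span)
    return chosen


# ---------------------------------------------------------------------------
# spacer matching
# ---------------------------------------------------------------------------

def match_spacers(arrays: list[CrisprArray], catalogue,
                  bins: pd.Series) -> list[HostLink]:
    """Exact full-length spacer-vs-virus matches on either strand.

    ``bins`` maps scaffold_id -> bin_id; arrays on unbinned scaffolds yield
    links flagged unbinned with host_bin_id "unbinned".
    """
    links: dict[tuple[str, str], list[str]] = {}
    flags: dict[tuple[str, str], bool] = {}
    for arr in arrays:
        bin_id = bins.get(arr.host_scaffold_id, None)
        unbinned = bin_id is None
        host = "unbinned" if unbinned else str(bin_id)
        for spacer, sp_lo, _ in arr.spacers:
            if len(spacer) < SPACER_LEN[0] or "N" in spacer:
                continue
            rc = revcomp(spacer)
            for v in catalogue:
                hits = []
                pos = v.seq.find(spacer)
                if pos >= 0:
                    hits.append((pos, "+"))
                pos = v.seq.find(rc)
                if pos >= 0:
                    hits.append((pos, "-"))
                for pos, strand in hits:
                    key = (v.viral_id, host)
                    links.setdefault(key, []).append(
                        f"spacer={spacer}@{arr.host_scaffold_id}:{sp_lo}"
                        f";protospacer_pos={pos};strand={strand}")
                    flags[key] = unbinned
    return [HostLink(vid, host, "spacer", "|".join(details), flags[(vid, host)])
            for (vid, host), details in sorted(links.items())]


# ---------------------------------------------------------------------------
# shared genomic content
# ---------------------------------------------------------------------------

def shared_content(virus, bin_scaffolds: dict[str, list],
                   cfg: PipelineConfig | None = None) -> list[HostLink]:
    """Link a virus to bins sharing a long, high-identity genomic region.

    The documented E-value clause of the source protocol is subsumed: any hit
    with >= 2.5 kb aligned at >= 70% identity has an astronomically small
    E-value, so length + identity + score are the binding constraints.
    """
    cfg = cfg or PipelineConfig()
    k = cfg.kmer_size
    vkmers = kmer_set(virus.seq, k) | kmer_set(revcomp(virus.seq), k)
    links = []
    for bin_id, scaffolds in sorted(bin_scaffolds.items()):
        best = None
        for s in scaffolds:
            if len(vkmers & kmer_set(s.seq, k)) < cfg.prefilter_min_shared_kmers:
                continue
            st = pairwise_ani(s, virus, k=k)
            if (st.aligned_len >= cfg.shared_content_min_len
                    and st.ani >= cfg.shared_content_min_identity
                    and st.score >= cfg.shared_content_min_score):
                if best is None or st.score > best[1].score:
                    best = (s.id, st)
        if best is not None:
            sid, st = best
            links.append(HostLink(
                virus.viral_id if hasattr(virus, "viral_id") else virus.id,
                bin_id, "shared_content",
                f"scaffold={sid};aligned_len={st.aligned_len};"
                f"identity={st.ani:.4f};score={st.score:.0f}"))
    return links


# ---------------------------------------------------------------------------
# prophage containment
# ---------------------------------------------------------------------------

def prophage_links(catalogue, bins: pd.Series) -> list[HostLink]:
    """One link per prophage whose parent scaffold belongs to a genome bin."""
    links = []
    for v in catalogue:
        if not v.is_prophage:
            continue
        bin_id = bins.get(v.parent_scaffold_id, None)
        if bin_id is None:
            links.append(HostLink(v.viral_id, "unbinned", "prophage",
                                  f"containing_scaffold={v.parent_scaffold_id}",
                                  unbinned=True))
        else:
            links.append(HostLink(v.viral_id, str(bin_id), "prophage",
                                  f"containing_scaffold={v.parent_scaffold_id}"))
    return links


def links_table(links: list[HostLink]) -> pd.DataFrame:
    rows = [{"virus_id": l.virus_id, "host_bin_id": l.host_bin_id,
             "evidence": l.evidence, "detail": l.detail,
             "unbinned": l.unbinned} for l in links]
    return pd.DataFrame(rows, columns=["virus_id", "host_bin_id", "evidence",
                                       "detail", "unbinned"])
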