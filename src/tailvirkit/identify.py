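"""Curation of predicted viral scaffolds.

Two upstream detectors feed this stage: a viral protein-family screen (whole
scaffolds >= 5 kb) and VirSorter (scaffolds >= 3 kb; categories 1-2 are
whole-scaffold calls, 4-5 carry a predicted prophage region). The module
merges the two call sets, trims prophage boundaries to the outermost
virus-hallmark gene, removes protein-family calls superseded by a prophage
prediction on the same scaffold, and applies the final acceptance filter:
a scaffold (or trimmed region) is kept if it carries a virus-specific gene or
if >= 80% of its genes have no functional assignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .config import PipelineConfig
from .io_formats import Gene, Scaffold, genes_by_scaffold

log = logging.getLogger("tailvirkit.identify")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class DetectorCall:
    """One upstream prediction that a scaffold (or sub-region) is viral."""
    scaffold_id: str
    detector: str                       # "protein_family" | "virsorter"
    virsorter_category: int | None = None
    prophage_region: tuple[int, int] | None = None  # 0-based half-open

    def __post_init__(self):
        if self.detector not in ("protein_family", "virsorter"):
            raise ValueError(f"unknown detector {self.detector!r}")
        if (self.virsorter_category is not None) != (self.detector == "virsorter"):
            raise ValueError("virsorter_category present iff detector is virsorter")
        is_prophage_cat = self.virsorter_category in (4, 5)
        if (self.prophage_region is not None) != is_prophage_cat:
            raise ValueError("prophage_region present iff category in {4, 5}")


@dataclass(frozen=True)
class GeneFlags:
    virus_specific: bool
    integrase: bool
    unknown: bool
    short: bool

    @property
    def hallmark(self) -> bool:
        """Virus-specific or integrase: the genes that anchor prophage trimming."""
        return self.virus_specific or self.integrase


@dataclass
class ViralScaffold:
    """A curated viral sequence: whole scaffold or trimmed prophage region."""
    viral_id: str
    parent_scaffold_id: str
    region: tuple[int, int]             # 0-based half-open on the parent
    is_prophage: bool
    detectors: frozenset
    genes: list[Gene]                   # restricted to region, sorted by start
    seq: str = ""
    accepted: bool = False
    reason: str = "rejected"            # virus_specific_gene | unknown_fraction | rejected

    @property
    def length(self) -> int:
        return self.region[1] - self.region[0]

    @property
    def id(self) -> str:
        """Alias so curated entries can stand in wherever a Scaffold is expected."""
        return self.viral_id


def prophage_viral_id(parent_id: str, start: int, end: int) -> str:
    return f"{parent_id}|prophage_{start}_{end}"


# ---------------------------------------------------------------------------
# gene classification
# ---------------------------------------------------------------------------

def classify_gene(g: Gene, cfg: PipelineConfig | None = None) -> GeneFlags:
    """Flag a gene as virus-specific / integrase / unknown / short.

    Keyword matching is case-insensitive and whole-token: the function text is
    lowercased and split on non-alphanumerics, so "head" does not fire inside
    "heady" and "t4" does not fire inside "t4ss". Two-word keywords match
    adjacent token pairs.
    """
    cfg = cfg or PipelineConfig()
    tokens = _TOKEN_RE.findall(g.function_text.lower())
    token_set = set(tokens)
    singles = set(cfg.virus_keywords_single)
    virus_specific = bool(token_set & singles)
    if not virus_specific and len(tokens) > 1:
        pairs = set(zip(tokens, tokens[1:]))
        virus_specific = bool(pairs & set(cfg.virus_keywords_pairs))
    integrase = "integrase" in token_set
    unknown = (not g.cog_id) and (
        g.function_text.strip().lower() in {s.lower() for s in cfg.unknown_synonyms})
    short = g.length < cfg.short_gene_len
    return GeneFlags(virus_specific, integrase, unknown, short)


# ---------------------------------------------------------------------------
# prophage boundary trimming
# ---------------------------------------------------------------------------

def trim_prophage(call: DetectorCall, genes: list[Gene],
                  cfg: PipelineConfig | None = None) -> tuple[int, int] | None:
    """Shrink a predicted prophage region to its outermost hallmark genes.

    Genes on the scaffold edges of the predicted region beyond the first or
    last virus-specific (or integrase) gene are dropped; the returned region
    spans from the start of the first such gene to the end of the last. If the
    region contains no hallmark gene the call is rejected (returns None).
    """
    if call.prophage_region is None:
        raise ValueError("call has no prophage region to trim")
    cfg = cfg or PipelineConfig()
    lo, hi = call.prophage_region
    inside = [g for g in genes if g.start >= lo and g.end <= hi]
    marks = [g for g in inside if classify_gene(g, cfg).hallmark]
    if not marks:
        return None
    return (min(g.start for g in marks), max(g.end for g in marks))


# ---------------------------------------------------------------------------
# merging, dedup, acceptance
# ---------------------------------------------------------------------------

def _region_genes(genes: list[Gene], region: tuple[int, int]) -> list[Gene]:
    lo, hi = region
    return [g for g in genes if g.start >= lo and g.end <= hi]


def merge_and_dedup(pf_calls: list[DetectorCall], vs_calls: list[DetectorCall],
                    scaffolds: dict[str, Scaffold], genes: list[Gene],
                    cfg: PipelineConfig | None = None) -> list[ViralScaffold]:
    """Merge the two detectors' calls into one set of candidate viral sequences.

    Length cutoffs are applied per detector (5 kb protein-family, 3 kb
    VirSorter). VirSorter categories 3 and 6 are discarded. A protein-family
    whole-scaffold call is dropped whenever any VirSorter prophage call exists
    on the same scaffold. Scaffolds called whole by both detectors yield one
    candidate with ``detectors == {protein_family, virsorter}``.
    """
    cfg = cfg or PipelineConfig()
    by_scaf = genes_by_scaffold(genes)

    pf_ids: set[str] = set()
    for c in pf_calls:
        if c.detector != "protein_family":
            raise ValueError(f"non-protein-family call in pf_calls: {c}")
        if scaffolds[c.scaffold_id].length < cfg.min_len_protein_family:
            continue
        if c.scaffold_id in pf_ids:
            raise ValueError(f"duplicate protein-family call on {c.scaffold_id}")
        pf_ids.add(c.scaffold_id)

    vs_whole: set[str] = set()
    vs_prophage: dict[str, list[tuple[int, int]]] = {}
    for c in vs_calls:
        if c.detector != "virsorter":
            raise ValueError(f"non-virsorter call in vs_calls: {c}")
        if scaffolds[c.scaffold_id].length < cfg.min_len_virsorter:
            continue
        if c.virsorter_category in (3, 6):
            log.info("discarding VirSorter category %d call on %s",
                     c.virsorter_category, c.scaffold_id)
            continue
        if c.virsorter_category in (1, 2):
            if c.scaffold_id in vs_whole:
                raise ValueError(f"duplicate VirSorter whole call on {c.scaffold_id}")
            vs_whole.add(c.scaffold_id)
        else:
            regions = vs_prophage.setdefault(c.scaffold_id, [])
            for (lo, hi) in regions:
                if c.prophage_region[0] < hi and lo < c.prophage_region[1]:
                    raise ValueError(
                        f"overlapping VirSorter prophage regions on {c.scaffold_id}")
            regions.append(c.prophage_region)
    conflict = vs_whole & set(vs_prophage)
    if conflict:
        raise ValueError(f"VirSorter whole + prophage calls on {sorted(conflict)}")

    out: list[ViralScaffold] = []
    # prophage regions, trimmed
    for sid, regions in sorted(vs_prophage.items()):
        scaf_genes = by_scaf.get(sid, [])
        for region in sorted(regions):
            call = DetectorCall(sid, "virsorter", 4, region)
            trimmed = trim_prophage(call, scaf_genes, cfg)
            if trimmed is None:
                log.info("prophage call on %s rejected: no hallmark gene in region", sid)
                continue
            vid = prophage_viral_id(sid, *trimmed)
            out.append(ViralScaffold(
                viral_id=vid, parent_scaffold_id=sid, region=trimmed,
                is_prophage=True, detectors=frozenset({"virsorter"}),
                genes=_region_genes(scaf_genes, trimmed),
                seq=scaffolds[sid].seq[trimmed[0]:trimmed[1]]))

    # whole-scaffold calls; pf call superseded by a prophage call on the scaffold
    whole_ids = (pf_ids - set(vs_prophage)) | vs_whole
    for sid in sorted(whole_ids):
        detectors = set()
        if sid in pf_ids:
            detectors.add("protein_family")
        if sid in vs_whole:
            detectors.add("virsorter")
        scaf = scaffolds[sid]
        out.append(ViralScaffold(
            viral_id=sid, parent_scaffold_id=sid, region=(0, scaf.length),
            is_prophage=False, detectors=frozenset(detectors),
            genes=by_scaf.get(sid, []), seq=scaf.seq))
    out.sort(key=lambda v: v.viral_id)
    return out


def accept_viral(v: ViralScaffold, cfg: PipelineConfig | None = None) -> ViralScaffold:
    """Apply the final acceptance filter in place and return the candidate.

    Accepted iff (1) any gene in the (possibly trimmed) region is
    virus-specific, or (2) the fraction of genes with no functional
    assignment is >= the unknown-fraction threshold (default 0.80).
    Clause (1) wins ties for the recorded reason. Zero genes -> rejected.
    """
    cfg = cfg or PipelineConfig()
    if not v.genes:
        v.accepted, v.reason = False, "rejected"
        return v
    flags = [classify_gene(g, cfg) for g in v.genes]
    if any(f.virus_specific for f in flags):
        v.accepted, v.reason = True, "virus_specific_gene"
    elif sum(f.unknown for f in flags) / len(flags) >= cfg.unknown_fraction_threshold:
        v.accepted, v.reason = True, "unknown_fraction"
    else:
        v.accepted, v.reason = False, "rejected"
    return v


def build_catalogue(pf_calls, vs_calls, scaffolds: dict[str, Scaffold],
                    genes, cfg: PipelineConfig | None = None):
    """Full curation: merge, trim, dedup, accept.

    Returns (accepted, rejected) lists of ViralScaffold.
    """
    cfg = cfg or PipelineConfig()
    candidates = merge_and_dedup(pf_calls, vs_calls, scaffolds, genes, cfg)
    accepted, rejected = [], []
    for v in candidates:
        accept_viral(v, cfg)
        (accepted if v.accepted else rejected).append(v)
    return accepted, rejected
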