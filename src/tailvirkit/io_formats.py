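"""Readers and writers for every external format the pipeline touches.

Sequences travel as FASTA (Biopython-backed), all tables as TSV with a header
row. Gene coordinates are 0-based half-open in memory everywhere; on disk they
are written 1-based inclusive (GFF3 convention) with the dialect recorded in a
``# coordinates: 1-based-inclusive`` header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA_ALPHABET

log = logging.getLogger("tailvirkit.io")

GENE_COLUMNS = ["scaffold_id", "gene_id", "start", "end", "strand",
                "cog_id", "function_text", "source_db"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """A nucleotide scaffold: unique id plus an uppercase ACGTN sequence."""
    id: str
    seq: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid scaffold id {self.id!r}")
        if not self.seq:
            raise ValueError(f"scaffold {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"scaffold {self.id}: characters outside ACGTN: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Gene:
    """One predicted gene with its functional annotation.

    ``start``/``end`` are 0-based half-open on the parent scaffold; length in
    nt is ``end - start``.
    """
    scaffold_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    cog_id: str = ""
    function_text: str = ""
    source_db: str = "none"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: bad interval ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SampleTable:
    """Per-sample metadata: core, depth, geochemistry, and library size."""
    table: pd.DataFrame  # index sample_id; columns: core, depth_cm, geochemistry...
    reads: pd.Series     # index sample_id -> library read count

    def __post_init__(self):
        if (self.reads <= 0).any():
            raise ValueError("library read counts must be positive")
        if "pH" in self.table.columns:
            ph = self.table["pH"]
            if ((ph <= 0) | (ph >= 14)).any():
                raise ValueError("pH out of (0, 14)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def geochemistry(self, parameters: list[str] | None = None) -> pd.DataFrame:
        drop = [c for c in ("core",) if c in self.table.columns]
        g = self.table.drop(columns=drop)
        return g[parameters] if parameters is not None else g


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Scaffold]:
    """Read a FASTA file into Scaffolds; uppercases, rejects non-ACGTN.

    Duplicate ids and empty records are hard errors naming the offender.
    """
    out, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(Scaffold(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(scaffolds, path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in scaffolds]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, one_based_inclusive: bool = True,
                    scaffold_ids: set[str] | None = None) -> list[Gene]:
    """Read a TSV gene table; convert coordinates to 0-based half-open.

    Rows referencing a scaffold absent from ``scaffold_ids`` (when given) are
    retained with a warning — validation is deferred to the consuming stage.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if one_based_inclusive:
            start -= 1
        if end <= start:
            raise ValueError(f"gene {row.gene_id}: end <= start after conversion")
        if scaffold_ids is not None and row.scaffold_id not in scaffold_ids:
            warnings.warn(f"gene {row.gene_id} references absent scaffold "
                          f"{row.scaffold_id}; retained for later validation")
        genes.append(Gene(row.scaffold_id, row.gene_id, start, end, row.strand,
                          row.cog_id, row.function_text, row.source_db or "none"))
    genes.sort(key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    return genes


def write_gene_table(genes, path: str | Path) -> None:
    """Write genes as TSV with 1-based inclusive coordinates (GFF3 dialect)."""
    rows = [{"scaffold_id": g.scaffold_id, "gene_id": g.gene_id,
             "start": g.start + 1, "end": g.end, "strand": g.strand,
             "cog_id": g.cog_id, "function_text": g.function_text,
             "source_db": g.source_db} for g in genes]
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based-inclusive\n")
        pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(fh, sep="\t", index=False)


def genes_by_scaffold(genes) -> dict[str, list[Gene]]:
    out: dict[str, list[Gene]] = {}
    for g in sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id)):
        out.setdefault(g.scaffold_id, []).append(g)
    return out


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path, reads_path: str | Path) -> SampleTable:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    reads = pd.read_csv(reads_path, sep="\t", index_col="sample_id")["reads"]
    reads = reads.reindex(meta.index)
    if reads.isna().any():
        missing = list(reads[reads.isna()].index)
        raise ValueError(f"samples missing library read counts: {missing}")
    return SampleTable(meta, reads.astype(int))


def read_coverage_long(path: str | Path) -> pd.DataFrame:
    """Long-format mapped-nucleotide counts: entity_id, sample_id, mapped_nt."""
    df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "sample_id": str})
    if (df["mapped_nt"] < 0).any():
        raise ValueError("negative mapped_nt")
    return df


def read_bins(path: str | Path) -> pd.Series:
    """scaffold_id -> bin_id; a scaffold in two bins is a hard error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    dup = df["scaffold_id"][df["scaffold_id"].duplicated()]
    if len(dup):
        raise ValueError(f"scaffold(s) assigned to multiple bins: {sorted(set(dup))}")
    return df.set_index("scaffold_id")["bin_id"]


def read_taxonomy(path: str | Path, key: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).set_index(key)


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """Prokaryotic OTU counts, OTUs x samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_detector_calls(path: str | Path):
    from .identify import DetectorCall  # local import to avoid a cycle
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls = []
    for row in df.itertuples(index=False):
        cat = int(row.virsorter_category) if row.virsorter_category else None
        region = None
        if row.region_start != "" and row.region_end != "":
            region = (int(row.region_start), int(row.region_end))
        calls.append(DetectorCall(row.scaffold_id, row.detector, cat, region))
    return calls


def write_detector_calls(calls, path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "scaffold_id": c.scaffold_id, "detector": c.detector,
            "virsorter_category": "" if c.virsorter_category is None else c.virsorter_category,
            "region_start": "" if c.prophage_region is None else c.prophage_region[0],
            "region_end": "" if c.prophage_region is None else c.prophage_region[1],
        })
    pd.DataFrame(rows, columns=["scaffold_id", "detector", "virsorter_category",
                                "region_start", "region_end"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# outputs + manifest
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config, seed: int, inputs: dict[str, str],
                   stage_counts: dict[str, int], versions: dict[str, str]) -> None:
    """Machine-readable run manifest: config echo, seed, input digests, counts."""
    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "inputs": inputs,
        "stage_order": ["identify", "cluster", "abundance", "hosts",
                        "functions", "stats"],
        "stage_counts": stage_counts,
        "versions": versions,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
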