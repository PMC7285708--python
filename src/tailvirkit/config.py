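"""Run configuration for the analysis pipeline.

All tunable thresholds live in a single :class:`PipelineConfig`, loadable from
a YAML key-value file. Defaults are the study's published operating points:
5 kb / 3 kb detector length cutoffs, the >=80% unknown-gene acceptance clause,
species-level vOTU clustering at 95% ANI over >=85% of the shorter sequence,
shared-content host linking at >=2.5 kb aligned, >=70% identity, score >= 50,
exact (zero-mismatch) CRISPR spacer matching, and BH-corrected alpha = 0.05
with 999 permutations for the permutation tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Phage-diagnostic annotation keywords. Single tokens are matched whole-word
#: (case-insensitive) against the gene's function text; two-word entries match
#: adjacent token pairs. "holing" is kept verbatim from the source vocabulary
#: and "holin" added as a synonym.
VIRUS_KEYWORDS_SINGLE = (
    "capsid", "phage", "terminase", "baseplate", "prohead", "virion",
    "holing", "holin", "virus", "viral", "tapemeasure", "neck", "tail",
    "p22", "head", "t4", "prophage",
)
VIRUS_KEYWORDS_PAIRS = (("base", "plate"), ("tape", "measure"))

#: function_text values that count as "no functional assignment".
UNKNOWN_SYNONYMS = ("", "hypothetical protein", "uncharacterized protein", "unknown")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage."""

    # viral identification
    min_len_protein_family: int = 5000      # nt; protein-family detector input cutoff
    min_len_virsorter: int = 3000           # nt; VirSorter detector input cutoff
    unknown_fraction_threshold: float = 0.80
    short_gene_len: int = 1000              # nt; genes below this are flagged "short"
    virus_keywords_single: tuple = VIRUS_KEYWORDS_SINGLE
    virus_keywords_pairs: tuple = VIRUS_KEYWORDS_PAIRS
    unknown_synonyms: tuple = UNKNOWN_SYNONYMS

    # vOTU clustering
    ani_threshold: float = 0.95
    af_threshold: float = 0.85
    kmer_size: int = 15
    prefilter_min_shared_kmers: int = 5

    # host prediction (shared genomic content)
    shared_content_evalue: float = 1e-3     # documented; subsumed by len+identity clauses
    shared_content_min_score: float = 50.0  # raw alignment score (+1/-2) surrogate for bit score
    shared_content_min_len: int = 2500      # nt
    shared_content_min_identity: float = 0.70
    spacer_mismatches: int = 0
    amg_cog: str = "COG0175"

    # statistics
    alpha: float = 0.05
    permutations: int = 999
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("unknown_fraction_threshold", "ani_threshold", "af_threshold",
                     "shared_content_min_identity", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_len_protein_family", "min_len_virsorter", "short_gene_len",
                     "shared_content_min_len", "permutations", "spacer_mismatches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["virus_keywords_single"] = list(d["virus_keywords_single"])
        d["virus_keywords_pairs"] = [list(p) for p in d["virus_keywords_pairs"]]
        d["unknown_synonyms"] = list(d["unknown_synonyms"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "virus_keywords_single" in d:
            d["virus_keywords_single"] = tuple(d["virus_keywords_single"])
        if "virus_keywords_pairs" in d:
            d["virus_keywords_pairs"] = tuple(tuple(p) for p in d["virus_keywords_pairs"])
        if "unknown_synonyms" in d:
            d["unknown_synonyms"] = tuple(d["unknown_synonyms"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
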