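"""Synthetic stratified mine-tailings community generator.

Emits a complete input bundle — assembly scaffolds, gene annotations,
detector calls, per-library coverage, host genome bins, CRISPR arrays,
geochemistry, and a prokaryotic OTU table — for an 11-sample, two-core design
(6 + 5 depth layers), together with a ground-truth record of everything
planted. The planted statistical structure mirrors a sulfidic tailings
impoundment:

* pH rises from ~2 at the surface to ~7 at depth; redox indicators
  (Fe2+/TFe up, SO4/TS down) track the oxidative-to-reductive transition;
* viral and prokaryotic richness increase with depth;
* prophage summed relative abundance is an affine function of pH (negative
  slope) plus noise;
* surface prokaryotic communities are archaea-dominated (Euryarchaeota ~67%
  and ~80% in the two top layers), deep layers bacteria-dominated;
* assimilatory-sulfate-reduction (COG0175) viral scaffolds are strongly
  deep-enriched, and indicator COGs are planted with a group-wise 8x effect.

Sequence evolution is i.i.d. per-site substitution (no indels), keeping
identity and alignment fraction analytically controllable. One root seed
feeds fixed-label child streams, so adding a feature never perturbs
existing draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import mutate, pairwise_mutation_rate, random_dna, revcomp
from .config import PipelineConfig
from .identify import DetectorCall, prophage_viral_id
from .io_formats import (Gene, SampleTable, Scaffold, write_detector_calls,
                         write_fasta, write_gene_table, write_tsv)

HALLMARK_TEXTS = (
    "major capsid protein", "phage terminase large subunit",
    "phage tail fiber protein", "baseplate assembly protein J",
    "prohead maturation protease", "virion structural protein",
    "tape measure protein", "phage neck appendage protein", "holin",
)
HOST_TEXTS = (
    "sulfate adenylyltransferase", "iron oxidase subunit", "ATP synthase F1 beta",
    "DNA polymerase III alpha", "cysteine desulfurase", "NADH dehydrogenase",
    "ribosomal protein L2", "heavy metal efflux pump", "carbonic anhydrase",
)
SURFACE_COGS = ("arCOG01244", "33PZW", "COG1397", "COG2365")
SURFACE_COG_TEXTS = ("archaeal integrase", "portal protein", "predicted membrane protein",
                     "protein of unknown family DUF1814")
DEEP_COGS = ("COG0175", "COG0675", "COG0305", "COG3723", "COG4974", "COG1961")
DEEP_COG_TEXTS = ("PAPS reductase / sulfonucleotide reductase", "transposase",
                  "replicative DNA helicase", "recombination protein RecT",
                  "site-specific tyrosine recombinase XerD", "serine recombinase")
ARCHAEAL_PHYLA = {"Euryarchaeota": 40, "Crenarchaeota": 15}
BACTERIAL_PHYLA = {"Proteobacteria": 70, "Nitrospirae": 30, "Firmicutes": 40,
                   "Actinobacteria": 35, "Chloroflexi": 25, "Bacteroidetes": 25,
                   "Planctomycetes": 20}
VIRAL_FAMILIES = ("Siphoviridae", "Podoviridae", "Myoviridae")


@dataclass
class SimConfig:
    """Generator knobs; defaults are the reference 11-sample study design."""
    n_cores: int = 2
    layers_per_core: tuple = (6, 5)
    rng_seed: int = 0
    n_host_bins: int = 10
    scaffolds_per_bin: int = 2
    host_scaffold_len: int = 12000
    n_viruses: int = 24                     # free viral ancestors (vOTU seeds)
    cluster_sizes: tuple = (3, 3, 2, 2)     # multi-member vOTUs; rest singletons
    n_prophages: int = 6
    n_amg_viruses: int = 3
    n_decoys: int = 3
    virus_len_range: tuple = (5000, 15000)
    within_votu_identity: float = 0.98
    between_votu_identity: float = 0.80
    prophage_share_intercept: float = 0.55
    prophage_pH_slope: float = -0.075       # share of viral community per pH unit
    prophage_noise_sd: float = 0.08
    amg_depth_enrichment: float = 8.0       # deep/surface coverage ratio, COG0175 carriers
    indicator_effect: float = 8.0           # group-wise fold change for planted indicators
    n_crispr_links: int = 4
    n_crispr_decoys: int = 2
    core_effect_sd: float = 0.6         # log-scale per-taxon core-B abundance shift
    read_count_range: tuple = (800_000, 1_300_000)
    n_prok_otus: int = 300
    prok_reads_range: tuple = (43_000, 135_000)

    def validate(self, ani_threshold: float = 0.95) -> None:
        if not (0 < self.between_votu_identity < ani_threshold
                < self.within_votu_identity < 1):
            raise ValueError(
                "need between_votu_identity < ani_threshold < within_votu_identity")
        if len(self.layers_per_core) != self.n_cores:
            raise ValueError("layers_per_core length must equal n_cores")
        if self.n_viruses < 12:
            raise ValueError("need at least 12 free viral ancestors")
        if self.n_prophages > self.n_host_bins:
            raise ValueError("at most one prophage per host bin")


@dataclass
class GroundTruth:
    """Everything planted, for oracle-style tests of the pipeline."""
    planted_viral_ids: set = field(default_factory=set)
    planted_prophage_ids: dict = field(default_factory=dict)   # viral_id -> bin_id
    planted_votu_partition: dict = field(default_factory=dict)  # viral_id -> label
    planted_spacer_links: set = field(default_factory=set)      # (virus_id, bin_id)
    planted_shared_links: set = field(default_factory=set)
    planted_amg_ids: set = field(default_factory=set)
    planted_indicator_cogs: dict = field(default_factory=dict)  # cog -> direction
    decoy_spacers: list = field(default_factory=list)
    decoy_scaffold_ids: set = field(default_factory=set)
    expected_relative_abundance: dict = field(default_factory=dict)
    expected_prok_composition: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)                  # sample -> surface|deep
    crispr_arrays: list = field(default_factory=list)           # (scaffold, start, n_repeats)

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, (set, frozenset)):
                return sorted(sorted(t) if isinstance(t, tuple) else t for t in o)
            raise TypeError(type(o))
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True, default=enc)
            fh.write("\n")


@dataclass
class Bundle:
    """In-memory synthetic input bundle (writable to disk via .write)."""
    scaffolds: list
    genes: list
    pf_calls: list
    vs_calls: list
    scaffold_coverage: pd.DataFrame     # long: entity_id, sample_id, mapped_nt
    gene_coverage: pd.DataFrame
    samples: SampleTable
    bins: pd.Series                     # scaffold_id -> bin_id
    bin_taxonomy: pd.DataFrame
    otu_table: pd.DataFrame             # OTUs x samples
    otu_taxonomy: pd.DataFrame
    viral_taxonomy: dict                # viral_id -> family
    ground_truth: GroundTruth

    def scaffold_dict(self) -> dict:
        return {s.id: s for s in self.scaffolds}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.scaffolds, outdir / "scaffolds.fasta")
        write_gene_table(self.genes, outdir / "genes.tsv")
        write_detector_calls(self.pf_calls + self.vs_calls,
                             outdir / "detector_calls.tsv")
        write_tsv(self.scaffold_coverage, outdir / "scaffold_coverage.tsv")
        write_tsv(self.gene_coverage, outdir / "gene_coverage.tsv")
        write_tsv(self.samples.table.reset_index(), outdir / "samples.tsv")
        write_tsv(self.samples.reads.rename("reads").rename_axis("sample_id")
                  .reset_index(), outdir / "library_reads.tsv")
        write_tsv(self.bins.rename("bin_id").rename_axis("scaffold_id").reset_index(),
                  outdir / "bins.tsv")
        write_tsv(self.bin_taxonomy.reset_index(), outdir / "bin_taxonomy.tsv")
        write_tsv(self.otu_table.rename_axis("otu_id").reset_index(),
                  outdir / "prokaryote_otus.tsv")
        write_tsv(self.otu_taxonomy.reset_index(), outdir / "prokaryote_taxonomy.tsv")
        write_tsv(pd.DataFrame(sorted(self.viral_taxonomy.items()),
                               columns=["viral_id", "family"]),
                  outdir / "viral_taxonomy.tsv")
        self.ground_truth.to_json(outdir / "ground_truth.json")


# ---------------------------------------------------------------------------
# focused planting operations (also used standalone as test oracles)
# ---------------------------------------------------------------------------

def plant_votus(rng: np.random.Generator, cluster_sizes, length: int = 5000,
                within: float = 0.98, between: float = 0.80,
                ani_threshold: float = 0.95, prefix: str = "pv"
                ) -> tuple[list, dict]:
    """Sequences with a known vOTU partition.

    Each cluster holds mutated copies of one ancestor at the within-cluster
    pairwise identity; ancestors are mutated copies of a common ur-sequence
    at the between-cluster pairwise identity. All sequences are full length,
    so alignment fractions are ~1.
    """
    if not (between < ani_threshold < within):
        raise ValueError("need between < ani_threshold < within")
    ur = random_dna(rng, length)
    s_b = pairwise_mutation_rate(between)
    s_w = pairwise_mutation_rate(within)
    seqs, partition = [], {}
    for c, size in enumerate(cluster_sizes):
        ancestor = mutate(rng, ur, s_b)
        for m in range(size):
            sid = f"{prefix}_c{c + 1}m{m + 1}"
            seqs.append(Scaffold(sid, mutate(rng, ancestor, s_w)))
            partition[sid] = f"cluster_{c + 1}"
    return seqs, partition


def plant_crispr(rng: np.random.Generator, host_seq: str, spacer_sources: list,
                 n_decoy_spacers: int = 0, all_viral_seqs: list | None = None,
                 insert_at: int = 500, repeat_len: int = 30
                 ) -> tuple[str, list, list]:
    """Embed one CRISPR array into a host sequence.

    ``spacer_sources`` lists (viral_seq, reverse_complement?) pairs; each
    yields one spacer copied verbatim (or reverse-complemented) from the
    virus. Decoy spacers are viral substrings with one central mismatch, so
    they can never produce an exact full-length match. Returns the modified
    host sequence, the real spacers, and the decoy spacers.
    """
    all_viral_seqs = all_viral_seqs or [s for s, _ in spacer_sources]
    if len(spacer_sources) + n_decoy_spacers < 2:
        raise ValueError("an array needs >= 2 spacers (>= 3 direct repeats)")
    repeat = random_dna(rng, repeat_len)
    spacers, decoys = [], []
    for vseq, rc in spacer_sources:
        ln = int(rng.integers(28, 41))
        pos = int(rng.integers(0, len(vseq) - ln))
        sp = vseq[pos:pos + ln]
        spacers.append(revcomp(sp) if rc else sp)
    for _ in range(n_decoy_spacers):
        vseq = all_viral_seqs[int(rng.integers(0, len(all_viral_seqs)))]
        ln = int(rng.integers(28, 41))
        pos = int(rng.integers(0, len(vseq) - ln))
        sp = list(vseq[pos:pos + ln])
        mid = ln // 2
        sp[mid] = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}[sp[mid]]
        decoys.append("".join(sp))
    order = spacers + decoys
    array = repeat + "".join(sp + repeat for sp in order)
    if insert_at + len(array) > len(host_seq):
        raise ValueError("host sequence too short for the array")
    new_seq = host_seq[:insert_at] + array + host_seq[insert_at + len(array):]
    return new_seq, spacers, decoys


# ---------------------------------------------------------------------------
# internal builders
# ---------------------------------------------------------------------------

def _design_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    ph_profiles = {"A": [2.1, 2.8, 3.9, 5.0, 6.0, 6.8],
                   "B": [2.3, 3.2, 4.5, 5.7, 6.9]}
    for core_i in range(cfg.n_cores):
        core = chr(ord("A") + core_i)
        n_layers = cfg.layers_per_core[core_i]
        base_ph = ph_profiles.get(core) or list(np.linspace(2.1, 6.9, n_layers))
        if len(base_ph) != n_layers:
            base_ph = list(np.linspace(2.1, 6.9, n_layers))
        for i in range(n_layers):
            t = i / max(n_layers - 1, 1)            # depth fraction in [0, 1]
            depth = 5 + i * 50 / max(n_layers - 1, 1) + (core_i)
            ph = base_ph[i] + float(rng.normal(0, 0.03))
            rows.append({
                "sample_id": f"{core}{i + 1}", "core": core,
                "depth_cm": round(depth, 1), "depth_frac": t,
                "pH": round(ph, 2),
                "EC": round(3.6 - 2.8 * t + float(rng.normal(0, 0.08)), 3),
                "TOC": round(0.18 + 0.55 * t + float(rng.normal(0, 0.02)), 3),
                "TP": round(0.021 + 0.1 * t + float(rng.normal(0, 0.004)), 4),
                "TS": round(4.2 - 1.1 * t + float(rng.normal(0, 0.1)), 3),
                "Fe2_TFe": round(float(np.clip(0.08 + 0.8 * t + rng.normal(0, 0.02),
                                               0.01, 0.99)), 3),
                "SO4_TS": round(float(np.clip(0.85 - 0.7 * t + rng.normal(0, 0.02),
                                              0.01, 0.99)), 3),
                "Pb": round(2800 + 900 * t + float(rng.normal(0, 60)), 1),
                "Zn": round(4100 - 700 * t + float(rng.normal(0, 80)), 1),
                "Cu": round(310 + 120 * t + float(rng.normal(0, 15)), 1),
            })
    df = pd.DataFrame(rows).set_index("sample_id")
    # enforce strict pH monotonicity with depth within each core
    for core, grp in df.groupby("core"):
        ph = np.maximum.accumulate(grp["pH"].values + np.arange(len(grp)) * 1e-3)
        df.loc[grp.index, "pH"] = np.round(ph, 3)
    return df


def _tile_genes(rng, scaffold_id: str, length: int, lo: int = 0, hi: int | None = None
                ) -> list[list]:
    """Gene coordinate slots [(start, end), ...] tiled over [lo, hi)."""
    hi = hi if hi is not None else length
    slots, pos = [], lo + int(rng.integers(10, 80))
    while pos + 600 <= hi:
        glen = int(rng.integers(600, 1400))
        end = min(pos + glen, hi)
        if end - pos >= 300:
            slots.append([pos, end])
        pos = end + int(rng.integers(20, 120))
    return slots


def _make_genes(rng, scaffold_id, slots, annotations) -> list:
    """annotations: list of (cog_id, function_text, source_db) per slot."""
    genes = []
    for i, ((start, end), (cog, text, db)) in enumerate(zip(slots, annotations)):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(scaffold_id, f"{scaffold_id}_g{i + 1}", start, end,
                          strand, cog, text, db))
    return genes


def _hyp() -> tuple:
    return ("", "hypothetical protein", "none")


# ---------------------------------------------------------------------------
# the bundle generator
# ---------------------------------------------------------------------------

def simulate_bundle(cfg: SimConfig | None = None,
                    pipeline_cfg: PipelineConfig | None = None,
                    outdir: str | Path | None = None) -> tuple[Bundle, GroundTruth]:
    """Generate the full synthetic input bundle plus its ground truth."""
    cfg = cfg or SimConfig()
    pcfg = pipeline_cfg or PipelineConfig()
    cfg.validate(ani_threshold=pcfg.ani_threshold)
    seed = cfg.rng_seed
    rng_geo = np.random.default_rng([seed, 1])
    rng_host = np.random.default_rng([seed, 2])
    rng_vir = np.random.default_rng([seed, 3])
    rng_cov = np.random.default_rng([seed, 4])
    rng_prok = np.random.default_rng([seed, 5])
    rng_crispr = np.random.default_rng([seed, 6])
    rng_gene = np.random.default_rng([seed, 7])
    rng_reads = np.random.default_rng([seed, 8])

    gt = GroundTruth()
    samples = _design_samples(cfg, rng_geo)
    sample_ids = list(samples.index)
    depth_frac = samples["depth_frac"]
    # analysis grouping: top two layers of each core are "surface"
    for core, grp in samples.groupby("core"):
        ordered = grp.sort_values("depth_cm").index
        for i, s in enumerate(ordered):
            gt.groups[s] = "surface" if i < 2 else "deep"
    groups = pd.Series(gt.groups)

    reads = pd.Series(
        rng_reads.integers(cfg.read_count_range[0], cfg.read_count_range[1],
                           size=len(sample_ids)),
        index=sample_ids, name="reads").astype(int)

    # ---------------- free viral scaffolds -------------------------------
    n = cfg.n_viruses
    n_amg, n_surf, n_deep = cfg.n_amg_viruses, 2, 4
    n_niche = max(3, round(0.375 * n))
    n_neutral = n - n_amg - n_surf - n_deep - n_niche
    classes = (["neutral"] * n_neutral + ["surface"] * n_surf
               + ["deep"] * n_deep + ["amg"] * n_amg + ["niche"] * n_niche)

    s_w = pairwise_mutation_rate(cfg.within_votu_identity)
    free: list[Scaffold] = []
    virus_class: dict[str, str] = {}
    niche_thresholds = np.linspace(0.25, 0.95, n_niche)
    niche_i = 0
    virus_niche: dict[str, float] = {}
    extra_sizes = list(cfg.cluster_sizes)
    for vi, vclass in enumerate(classes):
        lo, hi = cfg.virus_len_range
        length = int(rng_vir.integers(lo, hi))
        if vclass == "amg":
            length = max(length, 11000)     # ASR carriers are all > 10 kb
        elif vclass in ("surface", "deep"):
            length = max(length, 10000)     # room for every assigned COG gene
        ancestor = random_dna(rng_vir, length)
        size = extra_sizes.pop(0) if (extra_sizes and vclass in ("neutral", "niche")) else 1
        label = f"vclu_{vi + 1:03d}"
        for m in range(size):
            sid = f"virus_{vi + 1:03d}" + (f"m{m + 1}" if size > 1 else "")
            seq = ancestor if m == 0 else mutate(rng_vir, ancestor, s_w)
            free.append(Scaffold(sid, seq))
            virus_class[sid] = vclass
            gt.planted_votu_partition[sid] = label
            if vclass == "niche":
                virus_niche[sid] = float(niche_thresholds[niche_i])
        if vclass == "niche":
            niche_i += 1
        if vclass == "amg":
            pass
    amg_free = [s.id for s in free if virus_class[s.id] == "amg"]
    gt.planted_amg_ids = set(amg_free)

    # ---------------- host bins and prophages ----------------------------
    phyla = (["Euryarchaeota", "Euryarchaeota", "Crenarchaeota"]
             + list(BACTERIAL_PHYLA))[: cfg.n_host_bins]
    bins = {}
    bin_tax_rows = []
    host_scaffolds: list[Scaffold] = []
    host_seq_raw: dict[str, str] = {}
    for b in range(cfg.n_host_bins):
        bin_id = f"bin_{b + 1:02d}"
        domain = "Archaea" if phyla[b] in ARCHAEAL_PHYLA else "Bacteria"
        bin_tax_rows.append({"bin_id": bin_id, "domain": domain, "phylum": phyla[b],
                             "lineage": f"d__{domain};p__{phyla[b]}"})
        for k in range(cfg.scaffolds_per_bin):
            sid = f"host_{b + 1:02d}_{k + 1}"
            host_seq_raw[sid] = random_dna(rng_host, cfg.host_scaffold_len)
            bins[sid] = bin_id
    bin_taxonomy = pd.DataFrame(bin_tax_rows).set_index("bin_id")

    genes: list[Gene] = []
    vs_calls: list[DetectorCall] = []
    pf_calls: list[DetectorCall] = []
    prophage_ids: list[str] = []
    prophage_parent: dict[str, str] = {}

    # prophages integrated in scaffold 1 of the first n_prophages bins
    for p in range(cfg.n_prophages):
        parent = f"host_{p + 1:02d}_1"
        plen = int(rng_vir.integers(5200, 7200))
        region_lo = 2600
        pro_seq = random_dna(rng_vir, plen)
        seq = host_seq_raw[parent]
        seq = seq[:region_lo] + pro_seq + seq[region_lo + plen:]
        host_seq_raw[parent] = seq
        # genes: host flank | hallmark ... hallmark | host flank
        left = _tile_genes(rng_gene, parent, len(seq), 0, region_lo - 20)
        inner = _tile_genes(rng_gene, parent, len(seq), region_lo + 5,
                            region_lo + plen - 5)
        right = _tile_genes(rng_gene, parent, len(seq), region_lo + plen + 20)
        if len(inner) < 4:
            raise RuntimeError("prophage region too gene-poor")
        ann_left = [(f"COG5{p}{i:02d}", HOST_TEXTS[i % len(HOST_TEXTS)], "eggnog")
                    for i in range(len(left))]
        ann_right = [(f"COG6{p}{i:02d}", HOST_TEXTS[(i + 3) % len(HOST_TEXTS)], "eggnog")
                     for i in range(len(right))]
        ann_inner = [_hyp() for _ in inner]
        ann_inner[0] = ("", HALLMARK_TEXTS[p % len(HALLMARK_TEXTS)], "eggnog")
        ann_inner[-1] = ("", "phage terminase large subunit", "eggnog")
        ann_inner[-2] = ("", "integrase", "eggnog")
        slots = left + inner + right
        anns = ann_left + ann_inner + ann_right
        genes.extend(_make_genes(rng_gene, parent, slots, anns))
        true_lo, true_hi = inner[0][0], inner[-1][1]
        # predicted region is padded by one host gene on each side (trim test)
        pad_lo = left[-1][0] if left else max(0, true_lo - 300)
        pad_hi = right[0][1] if right else min(len(seq), true_hi + 300)
        vs_calls.append(DetectorCall(parent, "virsorter", 4, (pad_lo, pad_hi)))
        vid = prophage_viral_id(parent, true_lo, true_hi)
        prophage_ids.append(vid)
        prophage_parent[vid] = parent
        gt.planted_prophage_ids[vid] = bins[parent]
        gt.planted_votu_partition[vid] = f"vclu_pro_{p + 1}"
        if p == 0:
            # exercises the merge rule: a protein-family whole-scaffold call on a
            # scaffold with a prophage prediction must be dropped
            pf_calls.append(DetectorCall(parent, "protein_family"))

    # surface indicator COGs ride on the two surface-class free viruses only,
    # deep indicators on the deep + AMG classes, null COGs on neutral viruses
    cog_assignment: dict[str, list[tuple[str, str]]] = {s.id: [] for s in free}
    surf_carriers = [s.id for s in free if virus_class[s.id] == "surface"]
    for i, (cog, text) in enumerate(zip(SURFACE_COGS, SURFACE_COG_TEXTS)):
        for c in {surf_carriers[i % len(surf_carriers)],
                  surf_carriers[(i + 1) % len(surf_carriers)]}:
            cog_assignment[c].append((cog, text))
        gt.planted_indicator_cogs[cog] = "surface"
    deep_only = [s.id for s in free if virus_class[s.id] == "deep"]
    for i, (cog, text) in enumerate(zip(DEEP_COGS, DEEP_COG_TEXTS)):
        if cog == pcfg.amg_cog:
            for c in amg_free:
                cog_assignment[c].append((cog, text))
        else:
            for c in {deep_only[i % len(deep_only)],
                      deep_only[(i + 2) % len(deep_only)]}:
                cog_assignment[c].append((cog, text))
        gt.planted_indicator_cogs[cog] = "deep"
    null_cogs = [f"COG{1000 + i}" for i in range(12)]
    neutral = [s.id for s in free if virus_class[s.id] == "neutral"]
    for i, cog in enumerate(null_cogs):
        for c in {neutral[i % len(neutral)], neutral[(i + 1) % len(neutral)]}:
            cog_assignment[c].append((cog, "conserved protein", ))

    # free-virus genes + detector calls
    unknown_route = [s.id for s in free if virus_class[s.id] == "niche"][:4]
    for s in free:
        slots = _tile_genes(rng_gene, s.id, s.length)
        anns = [_hyp() for _ in slots]
        assigned = cog_assignment[s.id]
        if s.id in unknown_route:
            # accepted through the >=80%-unknown clause: no hallmark text and
            # at most 20% of genes functionally assigned
            max_assigned = max(1, int(len(slots) * 0.15))
            for i, (cog, text, *_) in enumerate(assigned[:max_assigned]):
                anns[1 + i] = (cog, text, "eggnog")
        else:
            n_hall = int(rng_gene.integers(2, 4))
            hall_idx = [0] + list(1 + rng_gene.choice(len(slots) - 1,
                                                      size=n_hall - 1, replace=False))
            stable = sum(s.id.encode())
            for i, hi_ in enumerate(sorted(set(hall_idx))):
                anns[hi_] = ("", HALLMARK_TEXTS[(i + stable) % len(HALLMARK_TEXTS)],
                             "eggnog")
            spots = [i for i in range(len(slots)) if anns[i] == _hyp()]
            for (cog, text, *_), spot in zip(assigned, spots):
                anns[spot] = (cog, text, "eggnog")
            if virus_class[s.id] == "amg" and pcfg.amg_cog in [a[0] for a in assigned]:
                # ensure the ASR gene is flanked by hallmark genes on both sides
                idx = next(i for i in range(len(anns)) if anns[i][0] == pcfg.amg_cog)
                if idx == len(slots) - 1 and idx >= 2:
                    anns[idx], anns[idx - 1] = anns[idx - 1], anns[idx]
                    idx -= 1
                anns[-1] = ("", "phage tail fiber protein", "eggnog")
        genes.extend(_make_genes(rng_gene, s.id, slots, anns))
        pf_calls.append(DetectorCall(s.id, "protein_family"))
        if rng_gene.random() < 0.6:
            vs_calls.append(DetectorCall(s.id, "virsorter",
                                         int(rng_gene.integers(1, 3)), None))
    gt.planted_viral_ids = {s.id for s in free} | set(prophage_ids)
    placed_cogs = {g.cog_id for g in genes if g.cog_id}
    unplaced = set(gt.planted_indicator_cogs) - placed_cogs
    if unplaced:
        raise RuntimeError(f"planted indicator COGs without genes: {unplaced}")

    # decoy microbial scaffolds with detector calls but non-viral annotation
    decoys = []
    for d in range(cfg.n_decoys):
        sid = f"decoy_{d + 1:02d}"
        decoys.append(Scaffold(sid, random_dna(rng_host, 6000)))
        slots = _tile_genes(rng_gene, sid, 6000)
        anns = [(f"COG7{d}{i:02d}", HOST_TEXTS[(i + d) % len(HOST_TEXTS)], "eggnog")
                for i in range(len(slots))]
        genes.extend(_make_genes(rng_gene, sid, slots, anns))
        gt.decoy_scaffold_ids.add(sid)
    pf_calls.append(DetectorCall("decoy_01", "protein_family"))
    vs_calls.append(DetectorCall("decoy_02", "virsorter", 2, None))
    vs_calls.append(DetectorCall("decoy_03", "virsorter", 3, None))  # discarded category

    # singleton-vOTU viruses for planted links, so ground-truth link sets stay
    # exact (cluster co-members of a target would legitimately also match)
    neutral_single = [v for v in neutral
                      if sum(l == gt.planted_votu_partition[v]
                             for l in gt.planted_votu_partition.values()) == 1]
    # shared genomic content: one free neutral virus shares 3 kb with bin_08
    sc_virus = neutral_single[0]
    sc_host = f"host_08_2"
    vseq = next(s.seq for s in free if s.id == sc_virus)
    region = mutate(rng_host, vseq[1000:4000], 0.05)     # ~95% identity
    hs = host_seq_raw[sc_host]
    host_seq_raw[sc_host] = hs[:4000] + region + hs[7000:]
    gt.planted_shared_links.add((sc_virus, bins[sc_host]))

    # CRISPR arrays: n_links arrays on binned scaffolds (scaffold 2 of a bin)
    link_viruses = [neutral_single[1],
                    [s.id for s in free if virus_class[s.id] == "deep"][0],
                    surf_carriers[0], amg_free[0]][: cfg.n_crispr_links]
    for i, vid in enumerate(link_viruses):
        host_sid = f"host_{i + 1:02d}_2"
        vseq = next(s.seq for s in free if s.id == vid)
        n_dec = 1 if i < cfg.n_crispr_decoys else 0
        # two spacers from the target virus keep the array at >= 3 repeats
        new_seq, spacers, decoy_sp = plant_crispr(
            rng_crispr, host_seq_raw[host_sid], [(vseq, i % 2 == 1), (vseq, False)],
            n_decoy_spacers=n_dec, all_viral_seqs=[s.seq for s in free],
            insert_at=8000)
        host_seq_raw[host_sid] = new_seq
        gt.planted_spacer_links.add((vid, bins[host_sid]))
        gt.decoy_spacers.extend(decoy_sp)
        gt.crispr_arrays.append((host_sid, 8000, 3 + n_dec))

    # host gene annotations for scaffolds not already annotated (prophage parents done)
    annotated = {g.scaffold_id for g in genes}
    for sid, seq in host_seq_raw.items():
        host_scaffolds.append(Scaffold(sid, seq))
        if sid in annotated:
            continue
        slots = _tile_genes(rng_gene, sid, len(seq))
        anns = [(f"COG8{i:03d}", HOST_TEXTS[i % len(HOST_TEXTS)], "eggnog")
                for i in range(len(slots))]
        genes.extend(_make_genes(rng_gene, sid, slots, anns))

    all_scaffolds = host_scaffolds + free + decoys
    all_scaffolds.sort(key=lambda s: s.id)
    genes.sort(key=lambda g: (g.scaffold_id, g.start))

    # ---------------- coverage ------------------------------------------
    t = depth_frac
    surface_mask = groups.reindex(sample_ids) == "surface"
    core_b = (samples["core"] == "B").values
    eff = cfg.indicator_effect
    cov = {}
    base = {}
    for s in free:
        base[s.id] = 2.0 * float(np.exp(rng_cov.normal(0, 0.25)))
    for s in free:
        vclass = virus_class[s.id]
        prof = np.ones(len(sample_ids))
        if vclass == "surface":
            prof = np.where(surface_mask.values, eff, 1.0)
        elif vclass in ("deep", "amg"):
            prof = np.where(surface_mask.values, 1.0, eff)
        elif vclass == "niche":
            prof = (t.values >= virus_niche[s.id]).astype(float) * 1.5
        # consistent per-virus abundance shift between the two cores
        m_b = float(np.exp(rng_cov.normal(0, cfg.core_effect_sd)))
        prof = prof * np.where(core_b, m_b, 1.0)
        noise = np.exp(rng_cov.normal(0, 0.10, size=len(sample_ids)))
        cov[s.id] = base[s.id] * prof * noise
    free_cov = pd.DataFrame(cov, index=sample_ids).T

    # prophage share of the viral community is affine in pH (negative slope)
    ph = samples["pH"].values
    q = (cfg.prophage_share_intercept + cfg.prophage_pH_slope * ph
         + rng_cov.normal(0, cfg.prophage_noise_sd, size=len(ph)))
    q = np.clip(q, 0.02, 0.90)
    free_total = free_cov.sum(axis=0).values
    prophage_total = q / (1 - q) * free_total
    w = np.exp(rng_cov.normal(0, 0.25, size=cfg.n_prophages))
    jitter = np.exp(rng_cov.normal(0, 0.08, size=(cfg.n_prophages, len(sample_ids))))
    core_m = np.exp(rng_cov.normal(0, cfg.core_effect_sd, size=cfg.n_prophages))
    wmat = (w[:, None] * jitter) * np.where(core_b[None, :], core_m[:, None], 1.0)
    wmat = wmat / wmat.sum(axis=0, keepdims=True)   # composition shifts, total fixed
    pro_cov = pd.DataFrame(wmat * prophage_total[None, :],
                           index=prophage_ids, columns=sample_ids)

    host_cov = pd.DataFrame(
        5.0 * np.exp(rng_cov.normal(0, 0.2, size=(len(host_scaffolds) + len(decoys),
                                                  len(sample_ids)))),
        index=[s.id for s in host_scaffolds] + [s.id for s in decoys],
        columns=sample_ids)

    viral_cov = pd.concat([free_cov, pro_cov])
    total = viral_cov.sum(axis=0)
    gt.expected_relative_abundance = {
        s: {"prophage": float(pro_cov[s].sum() / total[s])} for s in sample_ids}

    # viral taxonomy on a subset of vOTUs (classified fraction rises with depth)
    fam_targets = ([s.id for s in free if virus_class[s.id] == "deep"][:3]
                   + amg_free[:1] + neutral[1:3] + [surf_carriers[0]]
                   + [v for v in virus_niche if virus_niche[v] > 0.7][:2])
    viral_taxonomy = {}
    for i, vid in enumerate(fam_targets):
        fam = VIRAL_FAMILIES[i % len(VIRAL_FAMILIES)]
        label = gt.planted_votu_partition[vid]
        for other, lab in gt.planted_votu_partition.items():
            if lab == label:
                viral_taxonomy[other] = fam
    classified = [v for v in viral_cov.index if v in viral_taxonomy]
    for s in sample_ids:
        gt.expected_relative_abundance[s]["classified"] = float(
            viral_cov.loc[classified, s].sum() / total[s])

    # convert planted normalized coverage to mapped-nucleotide counts
    lengths = {s.id: s.length for s in all_scaffolds}
    for vid in prophage_ids:
        lo, hi = map(int, vid.rsplit("_", 2)[-2:])
        lengths[vid] = hi - lo
    mean_reads = float(reads.mean())
    cov_all = pd.concat([viral_cov, host_cov])
    rows = []
    for eid, row in cov_all.iterrows():
        for s in sample_ids:
            mapped = round(row[s] * lengths[eid] * reads[s] / mean_reads)
            rows.append((eid, s, int(mapped)))
    scaffold_coverage = pd.DataFrame(rows, columns=["entity_id", "sample_id", "mapped_nt"])

    # gene-level coverage follows the parent entity, with small noise
    pro_regions = {prophage_parent[vid]: (vid, *map(int, vid.rsplit("_", 2)[-2:]))
                   for vid in prophage_ids}
    grows = []
    for g in genes:
        parent = g.scaffold_id
        eid = parent
        if parent in pro_regions:
            vid, lo, hi = pro_regions[parent]
            if g.start >= lo and g.end <= hi:
                eid = vid
        crow = cov_all.loc[eid]
        gnoise = np.exp(rng_cov.normal(0, 0.05, size=len(sample_ids)))
        for j, s in enumerate(sample_ids):
            mapped = round(crow[s] * gnoise[j] * g.length * reads[s] / mean_reads)
            grows.append((g.gene_id, s, int(mapped)))
    gene_coverage = pd.DataFrame(grows, columns=["entity_id", "sample_id", "mapped_nt"])

    # ---------------- prokaryotic OTU table ------------------------------
    otu_rows, tax_rows = [], []
    phylum_pool = {**ARCHAEAL_PHYLA, **BACTERIAL_PHYLA}
    scale = cfg.n_prok_otus / sum(phylum_pool.values())
    otu_ids, otu_phyla = [], []
    for phylum, n_p in phylum_pool.items():
        for i in range(max(2, round(n_p * scale))):
            oid = f"OTU_{phylum[:4]}_{i + 1:03d}"
            otu_ids.append(oid)
            otu_phyla.append(phylum)
            tax_rows.append({"otu_id": oid, "phylum": phylum,
                             "domain": "Archaea" if phylum in ARCHAEAL_PHYLA
                             else "Bacteria"})
    otu_phyla = np.array(otu_phyla)
    n_otu = len(otu_ids)
    activation = rng_prok.uniform(0, 0.95, size=n_otu)
    activation[rng_prok.random(n_otu) < 0.15] = 0.0       # always-present community
    base_w = np.exp(rng_prok.normal(0, 1.0, size=n_otu))
    otu_core_m = np.exp(rng_prok.normal(0, cfg.core_effect_sd, size=n_otu))

    eury_start = {"A": 0.67, "B": 0.80}
    counts = {}
    for s in sample_ids:
        ts = float(depth_frac[s])
        core = samples.loc[s, "core"]
        decay = (1 - ts) ** 1.5          # surface value is planted exactly
        f_eury = 0.03 + (eury_start.get(core, 0.7) - 0.03) * decay
        f_cren = 0.12 * (1 - ts) + 0.02
        f_prot = 0.08 + 0.30 * ts
        f_nitr = 0.03 + 0.17 * ts
        f_firm = 0.04 + 0.18 * ts
        # archaeal fractions are planted exactly; the bacterial block is
        # scaled into whatever remains
        rest = max(1e-6, 1 - (f_eury + f_cren + f_prot + f_nitr + f_firm))
        others = {"Actinobacteria": 0.35, "Chloroflexi": 0.25,
                  "Bacteroidetes": 0.22, "Planctomycetes": 0.18}
        bact = {"Proteobacteria": f_prot, "Nitrospirae": f_nitr,
                "Firmicutes": f_firm}
        bact.update({k: rest * v for k, v in others.items()})
        bact_scale = (1 - f_eury - f_cren) / sum(bact.values())
        target = {"Euryarchaeota": f_eury, "Crenarchaeota": f_cren,
                  **{k: v * bact_scale for k, v in bact.items()}}
        active = activation <= ts + 1e-9
        w_core = base_w * (otu_core_m if core == "B" else 1.0)
        probs = np.zeros(n_otu)
        for phylum, f in target.items():
            mask = active & (otu_phyla == phylum)
            if not mask.any():
                mask = otu_phyla == phylum      # keep every phylum represented
            wsub = w_core * mask
            probs += f * wsub / wsub.sum()
        probs /= probs.sum()
        n_reads = int(rng_prok.integers(*cfg.prok_reads_range))
        counts[s] = rng_prok.multinomial(n_reads, probs)
        gt.expected_prok_composition[s] = {
            "Euryarchaeota": float(target["Euryarchaeota"]),
            "archaeal_fraction": float(target["Euryarchaeota"]
                                       + target["Crenarchaeota"])}
    otu_table = pd.DataFrame(counts, index=otu_ids)
    otu_taxonomy = pd.DataFrame(tax_rows).set_index("otu_id")

    sample_table = SampleTable(samples.drop(columns=["depth_frac"]), reads)
    bundle = Bundle(all_scaffolds, genes, pf_calls, vs_calls, scaffold_coverage,
                    gene_coverage, sample_table, pd.Series(bins), bin_taxonomy,
                    otu_table, otu_taxonomy, viral_taxonomy, gt)
    if outdir is not None:
        bundle.write(outdir)
    return bundle, gt
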