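"""End-to-end orchestration: identify -> cluster -> abundance -> hosts ->
functions -> stats, with TSV outputs and a machine-readable run manifest.

The pipeline consumes a :class:`~tailvirkit.synthetic.Bundle` (or the same
tables read from disk) and is deterministic given its inputs, the config, and
the statistics seed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import CoverageMatrix, normalized_coverage, relative_abundance, richness
from .clustering import greedy_cluster, membership_table, partition_of
from .config import PipelineConfig
from .functions import (amg_report, amg_table, cog_coverage, indicator_cogs,
                        indicator_table)
from .hosts import detect_crispr, links_table, match_spacers, prophage_links, shared_content
from .identify import build_catalogue
from .io_formats import (SampleTable, Scaffold, write_fasta, write_manifest, write_tsv)
from .stats import (anosim, bray_curtis, euclidean, mantel, pca, pcoa, pearson,
                    permanova)

log = logging.getLogger("tailvirkit.pipeline")

GEOCHEM_PARAMS = ["pH", "EC", "TOC", "TP", "TS", "Fe2_TFe", "SO4_TS", "Pb", "Zn", "Cu"]


@dataclass
class PipelineResult:
    catalogue: list
    rejected: list
    votus: list
    membership: pd.DataFrame
    viral_cov: pd.DataFrame         # viral entity x sample normalized coverage
    votu_cov: pd.DataFrame
    gene_cov: pd.DataFrame
    votu_richness: pd.Series
    relative_abundances: pd.DataFrame   # rows: prophage, classified, per-family
    host_links: pd.DataFrame
    indicators: list
    amg_reports: list
    groups: pd.Series
    stats_summary: dict
    ordinations: dict
    distances: dict
    counts: dict


def derive_groups(samples: SampleTable, n_surface_layers: int = 2) -> pd.Series:
    """Surface/deep grouping: the top ``n_surface_layers`` of each core are
    surface. The grouping is an analysis input, not an inference."""
    groups = {}
    for core, grp in samples.table.groupby("core"):
        ordered = grp.sort_values("depth_cm").index
        for i, s in enumerate(ordered):
            groups[s] = "surface" if i < n_surface_layers else "deep"
    return pd.Series(groups).reindex(samples.sample_ids)


def _viral_coverage_matrix(catalogue, coverage_long: pd.DataFrame,
                           scaffolds: dict, reads: pd.Series) -> CoverageMatrix:
    """Coverage for curated entities; prophage rows fall back to the parent
    scaffold's counts scaled by region length when absent from the input."""
    lengths = pd.Series({v.viral_id: v.length for v in catalogue})
    have = set(coverage_long["entity_id"])
    extra = []
    for v in catalogue:
        if v.viral_id in have or v.parent_scaffold_id not in have:
            continue
        parent = coverage_long[coverage_long["entity_id"] == v.parent_scaffold_id]
        frac = v.length / scaffolds[v.parent_scaffold_id].length
        for row in parent.itertuples(index=False):
            extra.append((v.viral_id, row.sample_id, row.mapped_nt * frac))
    if extra:
        coverage_long = pd.concat(
            [coverage_long, pd.DataFrame(extra, columns=coverage_long.columns)])
    return CoverageMatrix.from_long(coverage_long, lengths, reads,
                                    entities=[v.viral_id for v in catalogue])


def run_all(bundle, cfg: PipelineConfig | None = None, seed: int | None = None,
            outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on an input bundle; optionally write all outputs."""
    cfg = cfg or PipelineConfig()
    seed = cfg.rng_seed if seed is None else seed
    scaffolds = bundle.scaffold_dict()
    samples = bundle.samples
    reads = samples.reads

    log.info("[identify] %d pf + %d vs calls", len(bundle.pf_calls), len(bundle.vs_calls))
    catalogue, rejected = build_catalogue(bundle.pf_calls, bundle.vs_calls,
                                          scaffolds, bundle.genes, cfg)

    log.info("[cluster] %d accepted viral sequences", len(catalogue))
    votus = greedy_cluster(catalogue, cfg, taxonomy=bundle.viral_taxonomy)
    membership = membership_table(votus)
    partition = partition_of(votus)

    log.info("[abundance]")
    viral_cm = _viral_coverage_matrix(catalogue, bundle.scaffold_coverage,
                                      scaffolds, reads)
    viral_cov = normalized_coverage(viral_cm)
    votu_cov = normalized_coverage(viral_cm.aggregate(partition))
    votu_rich = richness(votu_cov)

    viral_genes = [g for v in catalogue for g in v.genes]
    gene_lengths = pd.Series({g.gene_id: g.length for g in viral_genes})
    gene_ids = list(gene_lengths.index)
    gene_cm = CoverageMatrix.from_long(
        bundle.gene_coverage[bundle.gene_coverage["entity_id"].isin(gene_ids)],
        gene_lengths, reads, entities=gene_ids)
    gene_cov = normalized_coverage(gene_cm)

    ra_rows = {}
    prophage_ids = [v.viral_id for v in catalogue if v.is_prophage]
    ra_rows["prophage"] = relative_abundance(prophage_ids, viral_cov)
    classified = [v.viral_id for v in catalogue if v.viral_id in bundle.viral_taxonomy]
    ra_rows["classified"] = relative_abundance(classified, viral_cov)
    for fam in sorted(set(bundle.viral_taxonomy.values())):
        ids = [v for v in classified if bundle.viral_taxonomy[v] == fam]
        ra_rows[f"family:{fam}"] = relative_abundance(ids, viral_cov)
    rel_ab = pd.DataFrame(ra_rows).T

    log.info("[hosts]")
    catalogue_ids = {v.parent_scaffold_id for v in catalogue if not v.is_prophage}
    microbial = [s for s in bundle.scaffolds if s.id not in catalogue_ids]
    arrays = [a for s in microbial for a in detect_crispr(s)]
    links = match_spacers(arrays, catalogue, bundle.bins)
    links += prophage_links(catalogue, bundle.bins)
    bin_scaffolds: dict[str, list] = {}
    for sid, bin_id in bundle.bins.items():
        bin_scaffolds.setdefault(bin_id, []).append(scaffolds[sid])
    for v in catalogue:
        if not v.is_prophage:
            links += shared_content(v, bin_scaffolds, cfg)
    host_links = links_table(links)

    log.info("[functions]")
    groups = derive_groups(samples)
    cog_mat = cog_coverage(viral_genes, gene_cov)
    carriers: dict[str, set] = {}
    gene_owner = {g.gene_id: v.viral_id for v in catalogue for g in v.genes}
    for g in viral_genes:
        if g.cog_id:
            carriers.setdefault(g.cog_id, set()).add(gene_owner[g.gene_id])
    carriers = {k: frozenset(v) for k, v in carriers.items()}
    indicators = indicator_cogs(cog_mat, groups, cfg.alpha, carriers)
    amg_reports = amg_report(catalogue, viral_cov, gene_cov, groups, cfg)

    log.info("[stats]")
    geochem = samples.table[[c for c in GEOCHEM_PARAMS if c in samples.table.columns]]
    otu_rel = bundle.otu_table.div(bundle.otu_table.sum(axis=0), axis=1)
    prok_rich = (bundle.otu_table > 0).sum(axis=0)
    d_prok = bray_curtis(otu_rel.T.loc[samples.sample_ids])
    d_geo = euclidean(geochem)
    cores = samples.table["core"]
    ph = samples.table["pH"]
    perm, sseed = cfg.permutations, seed

    keys = ["anosim_R_core", "anosim_p_core", "permanova_F_core",
            "permanova_R2_core", "permanova_p_core", "anosim_R_depth",
            "anosim_p_depth", "permanova_F_depth", "permanova_R2_depth",
            "permanova_p_depth", "mantel_r_viral_prok", "mantel_p_viral_prok",
            "mantel_r_viral_geochem", "mantel_p_viral_geochem",
            "pearson_r_richness", "pearson_p_richness", "pearson_r_richness_pH",
            "pearson_p_richness_pH", "pearson_r_total_cov_pH",
            "pearson_p_total_cov_pH", "pearson_r_prophage_pH",
            "pearson_p_prophage_pH"]
    stats_summary = dict.fromkeys(keys, float("nan"))
    ordinations = {"pca_geochem": pca(geochem.pipe(lambda t: (t - t.mean()) / t.std(ddof=1))),
                   "pcoa_prok": pcoa(d_prok)}
    distances = {"prok_bray_curtis": d_prok, "geochem_euclidean": d_geo}

    if catalogue:   # viral statistics are undefined on an empty catalogue
        d_viral = bray_curtis(votu_cov.T.loc[samples.sample_ids])
        r_core, p_core = anosim(d_viral, cores, perm, sseed)
        f_core, r2_core, p_perm_core = permanova(d_viral, cores, perm, sseed)
        r_depth, p_depth = anosim(d_viral, groups, perm, sseed)
        f_depth, r2_depth, p_perm_depth = permanova(d_viral, groups, perm, sseed)
        mantel_vp = mantel(d_viral, d_prok, perm, sseed)
        mantel_vg = mantel(d_viral, d_geo, perm, sseed)
        total_cov = viral_cov.sum(axis=0)
        pro_ra = rel_ab.loc["prophage"]
        stats_summary.update({
            "anosim_R_core": r_core, "anosim_p_core": p_core,
            "permanova_F_core": f_core, "permanova_R2_core": r2_core,
            "permanova_p_core": p_perm_core,
            "anosim_R_depth": r_depth, "anosim_p_depth": p_depth,
            "permanova_F_depth": f_depth, "permanova_R2_depth": r2_depth,
            "permanova_p_depth": p_perm_depth,
            "mantel_r_viral_prok": mantel_vp[0], "mantel_p_viral_prok": mantel_vp[1],
            "mantel_r_viral_geochem": mantel_vg[0],
            "mantel_p_viral_geochem": mantel_vg[1]})
        for key, (x, y) in {
            "richness": (votu_rich[samples.sample_ids], prok_rich[samples.sample_ids]),
            "richness_pH": (votu_rich[samples.sample_ids], ph),
            "total_cov_pH": (total_cov[samples.sample_ids], ph),
            "prophage_pH": (pro_ra[samples.sample_ids], ph),
        }.items():
            try:
                r, p = pearson(x, y)
            except ValueError:
                r = p = float("nan")
            stats_summary[f"pearson_r_{key}"] = r
            stats_summary[f"pearson_p_{key}"] = p
        ordinations["pcoa_viral"] = pcoa(d_viral)
        distances["viral_bray_curtis"] = d_viral
    n_single = sum(len(v.detectors) == 1 for v in catalogue)
    counts = {
        "catalogue_size": len(catalogue),
        "catalogue_single_detector": n_single,
        "catalogue_both_detectors": len(catalogue) - n_single,
        "rejected": len(rejected),
        "n_votus": len(votus),
        "n_crispr_arrays": len(arrays),
        "links_spacer": int((host_links["evidence"] == "spacer").sum()),
        "links_prophage": int((host_links["evidence"] == "prophage").sum()),
        "links_shared_content": int((host_links["evidence"] == "shared_content").sum()),
        "n_indicator_cogs": sum(r.significant for r in indicators),
        "n_amg_scaffolds": len(amg_reports),
    }

    result = PipelineResult(catalogue, rejected, votus, membership, viral_cov,
                            votu_cov, gene_cov, votu_rich, rel_ab, host_links,
                            indicators, amg_reports, groups, stats_summary,
                            ordinations, distances, counts)
    if outdir is not None:
        write_outputs(result, bundle, cfg, seed, outdir)
    return result


def write_outputs(result: PipelineResult, bundle, cfg: PipelineConfig,
                  seed: int, outdir: str | Path) -> None:
    """Write every pipeline product as headered TSV/FASTA plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cat_rows = [{"viral_id": v.viral_id, "parent_scaffold_id": v.parent_scaffold_id,
                 "region_start": v.region[0], "region_end": v.region[1],
                 "is_prophage": v.is_prophage,
                 "detectors": ",".join(sorted(v.detectors)),
                 "n_genes": len(v.genes), "accepted": v.accepted,
                 "reason": v.reason} for v in result.catalogue + result.rejected]
    write_tsv(pd.DataFrame(cat_rows, columns=["viral_id", "parent_scaffold_id",
                                              "region_start", "region_end",
                                              "is_prophage", "detectors", "n_genes",
                                              "accepted", "reason"]),
              outdir / "catalogue.tsv")
    write_fasta([Scaffold(v.viral_id, v.seq) for v in result.catalogue],
                outdir / "catalogue.fasta")
    write_tsv(result.membership, outdir / "votus.tsv")
    write_tsv(result.viral_cov.rename_axis("entity_id").reset_index(),
              outdir / "coverage_viral.tsv")
    write_tsv(result.votu_cov.rename_axis("votu_id").reset_index(),
              outdir / "coverage_votu.tsv")
    write_tsv(result.relative_abundances.rename_axis("group").reset_index(),
              outdir / "relative_abundance.tsv")
    write_tsv(result.votu_richness.rename("votu_richness").rename_axis("sample_id")
              .reset_index(), outdir / "richness.tsv")
    write_tsv(result.host_links, outdir / "host_links.tsv")
    write_tsv(indicator_table(result.indicators), outdir / "indicator_cogs.tsv")
    write_tsv(amg_table(result.amg_reports), outdir / "amg_report.tsv")
    for name, ord_res in result.ordinations.items():
        write_tsv(ord_res.coordinates.rename_axis("sample_id").reset_index(),
                  outdir / f"ordination_{name}.tsv")
    for name, dm in result.distances.items():
        write_tsv(pd.DataFrame(dm.d, index=dm.sample_ids, columns=dm.sample_ids)
                  .rename_axis("sample_id").reset_index(),
                  outdir / f"distance_{name}.tsv")
    write_tsv(pd.DataFrame(sorted(result.stats_summary.items()),
                           columns=["statistic", "value"]),
              outdir / "stats_summary.tsv")
    write_manifest(outdir / "manifest.json", cfg, seed,
                   inputs={}, stage_counts=result.counts,
                   versions={"tailvirkit": __version__,
                             "python": sys.version.split()[0]})


def demo(seed: int = 0, outdir: str | Path | None = None) -> str:
    """Generate a bundle, run the full pipeline, and render a text report."""
    from .synthetic import SimConfig, simulate_bundle
    cfg = PipelineConfig(rng_seed=seed)
    bundle, gt = simulate_bundle(SimConfig(rng_seed=seed), cfg)
    res = run_all(bundle, cfg, seed=seed, outdir=outdir)
    s = res.stats_summary
    lines = [
        f"tailvirkit demo (seed={seed})",
        f"  curated viral sequences: {res.counts['catalogue_size']} "
        f"({res.counts['catalogue_both_detectors']} called by both detectors), "
        f"{res.counts['n_votus']} vOTUs",
        f"  vOTU richness range: {res.votu_richness.min()}-{res.votu_richness.max()}",
        f"  host links: {res.counts['links_spacer']} spacer, "
        f"{res.counts['links_prophage']} prophage, "
        f"{res.counts['links_shared_content']} shared-content",
        f"  richness coupling (viral vs prokaryotic): Pearson r = "
        f"{s['pearson_r_richness']:.2f} (p = {s['pearson_p_richness']:.3g})",
        f"  prophage relative abundance vs pH: Pearson r = "
        f"{s['pearson_r_prophage_pH']:.2f} (p = {s['pearson_p_prophage_pH']:.3g})",
        f"  viral vs prokaryotic community: Mantel r = "
        f"{s['mantel_r_viral_prok']:.2f} (p = {s['mantel_p_viral_prok']:.3g})",
        f"  viral vs geochemistry: Mantel r = {s['mantel_r_viral_geochem']:.2f}",
        f"  core A vs B: ANOSIM R = {s['anosim_R_core']:.2f}, "
        f"PERMANOVA R2 = {s['permanova_R2_core']:.2f}",
        f"  indicator COGs (q < {PipelineConfig().alpha}): "
        f"{res.counts['n_indicator_cogs']}",
        f"  COG0175 (ASR) viral scaffolds: {res.counts['n_amg_scaffolds']}: "
        + ", ".join(r.viral_id for r in res.amg_reports),
    ]
    return "\n".join(lines)
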