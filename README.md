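# tailvirkit

Depth-stratified viral metagenomics for extreme, geochemically zoned
environments — built around sulfidic mine-tailings cores, where progressive
sulfide oxidation creates steep vertical gradients (pH ~2 at the oxidized
surface to ~7 in unaltered deep layers) that stratify both prokaryotic and
viral communities.

The package is for microbial ecologists who already have assembly-level
products in hand — scaffolds, gene annotations, viral detector calls, read
mapping summaries, genome bins — and want the analysis layer: a curated viral
catalogue, species-level viral populations, abundance profiles, virus–host
links, depth-indicator gene functions, and the community-ecology statistics
that tie it all to geochemistry.

## What it computes

**Viral catalogue curation.** Calls from two upstream detectors (a viral
protein-family screen on scaffolds ≥ 5 kb; VirSorter on scaffolds ≥ 3 kb) are
merged. VirSorter categories 1–2 are whole-scaffold calls; for categories 4–5
only the predicted prophage region is kept, trimmed back to its outermost
*virus-specific* gene — one whose annotation contains a phage-diagnostic
keyword (capsid, terminase, baseplate, tail, virion, …, matched whole-token)
— or integrase. A protein-family call is dropped when a prophage is predicted
on the same scaffold. A candidate is accepted if it carries a virus-specific
gene, or if ≥ 80% of its genes have no functional assignment.

**vOTU clustering.** Curated sequences are clustered greedily
(longest-first, UCLUST-style) into viral operational taxonomic units at the
species-level operating point

> ANI ≥ 95% over ≥ 85% of the shorter sequence,

where ANI is computed by a seeded aligner (exact 15-mer anchors, diagonal
chaining, gapless x-drop extension, merged segments) validated against full
dynamic programming.

**Abundance.** Normalized coverage of an entity *e* in library *ℓ* is

```
cov(e, ℓ) = (mapped_nt(e, ℓ) / length(e)) / reads(ℓ) × mean(reads)
```

Relative abundance of a group of viruses in a sample is its summed
normalized coverage over the viral community total; richness is the count of
vOTUs present in a layer.

**Virus–host links.** Three evidence types: CRISPR spacers (arrays of ≥ 3
exact direct repeats, 23–47 nt, spacers 20–50 nt) matching a virus exactly
over the whole spacer on either strand; prophage containment in a binned
scaffold; and shared genomic content (≥ 2.5 kb aligned, ≥ 70% identity,
score ≥ 50).

**Functional profiles.** Per-COG normalized coverage is compared between
surface and deep layer groups with an exact two-sided Wilcoxon rank-sum test
(complete enumeration with mid-ranks for ties) and Benjamini–Hochberg
correction; COGs at q < 0.05 are *indicator COGs*. Viral scaffolds carrying
COG0175 (PAPS reductase — assimilatory sulfate reduction) are reported as
putative auxiliary metabolic genes with per-layer coverage and
hallmark-flanking status.

**Community statistics.** Bray–Curtis dissimilarities (communities),
Euclidean distances on z-scored geochemistry, PCA/PCoA, ANOSIM R, PERMANOVA
pseudo-F and R², Mantel correlations, and Pearson correlations — all
permutation p-values use the add-one convention with a seeded generator, and
every permutation test has an exhaustive-enumeration mode used by the test
suite.

**Synthetic community generator.** `tailvirkit.synthetic` emits a complete
input bundle for the reference 11-sample, two-core design (6 + 5 layers)
with planted ground truth: the pH/redox gradients, archaea-dominated surface
(Euryarchaeota 67%/80% in the two top layers), richness increasing with
depth, prophage relative abundance affine in pH with negative slope,
8×-effect indicator COGs, deep-enriched COG0175 carriers, planted vOTU
partitions, and planted CRISPR links with single-mismatch decoys.

## Worked example

```sh
tailvirkit demo --seed 0
```

prints (computed live; every number re-derives from the seed):

```
tailvirkit demo (seed=0)
  curated viral sequences: 36 (16 called by both detectors), 30 vOTUs
  vOTU richness range: 21-30
  host links: 4 spacer, 6 prophage, 1 shared-content
  richness coupling (viral vs prokaryotic): Pearson r = 0.96 (p = 2.58e-06)
  prophage relative abundance vs pH: Pearson r = -0.92 (p = 4.95e-05)
  viral vs prokaryotic community: Mantel r = 0.77 (p = 0.001)
  viral vs geochemistry: Mantel r = 0.73
  core A vs B: ANOSIM R = 0.14, PERMANOVA R2 = 0.07
  indicator COGs (q < 0.05): 10
  COG0175 (ASR) viral scaffolds: 3: virus_013, virus_014, virus_015
```

Reading it: all 36 planted viral sequences (including 6 trimmed prophages)
were curated and collapse into 30 species-level vOTUs; richness climbs from
21 vOTUs at the surface to 30 at depth in step with prokaryotic richness
(r = 0.96); prophages concentrate in the acidic surface layers (negative
correlation with pH — the lysogeny-under-stress signal); viral community
turnover tracks both host communities and geochemistry (Mantel r); and the
ten planted depth-indicator COGs, including the deep-enriched assimilatory
sulfate reduction gene on three >10 kb viral scaffolds, are all recovered.

The `examples/` directory holds one short narrative script per capability;
each builds or loads a small input, runs the method, and explains the
numbers it prints. The same pipeline is scriptable from the shell:

```sh
tailvirkit simulate --seed 0 --outdir bundle/
tailvirkit run-all bundle/ --seed 0 --outdir results/
```

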