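# Methods

This note documents the models, rules, and numerical choices behind
tailvirkit, and what the synthetic-data tests do and do not demonstrate.

## Viral catalogue curation

Candidate viral sequences come from two upstream detectors whose outputs are
*inputs* to this package: a viral protein-family screen (whole scaffolds,
minimum 5,000 nt) and VirSorter (minimum 3,000 nt; categories 1–2 =
whole-scaffold, 4–5 = prophage region, 3 and 6 discarded). The merge rules:

* A protein-family whole-scaffold call is dropped whenever any VirSorter
  prophage call exists on the same scaffold (the prophage prediction is the
  more specific claim).
* When both detectors call the same scaffold whole, one candidate is kept
  with both detectors recorded; VirSorter whole-scaffold calls are never
  trimmed.
* Prophage regions are trimmed to span from the first to the last
  *hallmark* gene (virus-specific or integrase) fully inside the predicted
  region; a region without a hallmark gene is rejected. Trimming never
  enlarges a region and is idempotent.

**Keyword matching.** The hallmark vocabulary (capsid, phage, terminase,
baseplate / "base plate", prohead, virion, holing, holin, virus, viral,
"tape measure"/tapemeasure, neck, tail, p22, head, T4, prophage) is matched
case-insensitively against whole tokens of the function text after splitting
on non-alphanumerics; two-word entries match adjacent token pairs. The
original screening protocol applied these keywords with manual curation; a
bare substring rule would let "head" fire inside "heady" and "T4" inside
"T4SS", so the whole-token rule is the conservative mechanical replacement
for that human judgment. "holing" is kept verbatim from the printed
vocabulary and "holin" added as a synonym (the former is almost certainly a
typo for the latter); both are configurable.

**Unknown genes.** A gene is *unknown* when it has no COG assignment and its
function text is empty or a configured synonym of "hypothetical protein".
The acceptance filter keeps a candidate iff it has ≥ 1 virus-specific gene
or ≥ 80% unknown genes, computed over the genes of the (possibly trimmed)
region — the trimmed-region reading was chosen because the trimmed genes are
the claim being tested. Zero genes ⇒ rejected (the fraction is undefined).

## Pairwise ANI and vOTU clustering

The aligner finds exact 15-mer anchors (k-mers containing N are skipped;
k-mers occurring > 20 times in the subject are repeat-masked), groups them by
diagonal, clusters anchors < 200 nt apart, extends each cluster gaplessly in
both directions under an x-drop of 20 with +1/−2 match/mismatch scores,
merges per-diagonal overlaps, and greedily selects non-overlapping segments
by score. ANI = identities / aligned columns over the selected segments; the
alignment fraction divides aligned columns by the length of the *shorter*
sequence, so containment scores AF ≈ 1. Ns never count as matches. Both
orientations are aligned and the better kept. Sequences shorter than k fall
back to plain Needleman–Wunsch (gap −3).

The test suite holds this heuristic to ±0.01 of full dynamic programming
(Biopython's C aligner). Local-mode DP is the oracle for all pairs;
global-mode DP is additionally checked on full-length pairs — on truncated,
diverged pairs global DP shifts mismatch-dense flanks into terminal gaps,
which is a property of that convention rather than an aligner error.

Clustering is greedy longest-first (ties broken lexicographically): each
unassigned sequence seeds a vOTU and absorbs every remaining sequence with
ANI ≥ 0.95 and AF ≥ 0.85 against the seed. The seed is therefore the
representative, membership conditions are checkable against it, and the
output is invariant to input order. A pair sharing < 5 distinct 15-mers
(either strand) is treated as ANI 0 without alignment; a genuine 95%-ANI pair
of ≥ 3 kb shares hundreds.

## Abundance model

Normalized coverage: (mapped nucleotides / entity length) / library reads ×
mean reads over the libraries present in the input (recomputed per run).
vOTU-level coverage pools members *before* normalization — summed mapped
nucleotides over summed lengths — i.e. coverage-weighted pooling. Richness
counts vOTUs with normalized coverage above a presence threshold (default 0,
configurable; no detection cutoff is imposed by default). Relative abundance
of a virus group in a sample divides its summed normalized coverage by the
sample's viral total; a sample with zero viral signal yields a missing value.
Prophage entities absent from the coverage input fall back to the parent
scaffold's counts scaled by region length.

## Virus–host linking

* **CRISPR.** Arrays are maximal runs of ≥ 3 *exact* direct repeats
  (23–47 nt) alternating with spacers (20–50 nt); overlapping candidates are
  resolved by most repeats, then longest span. Exact-repeat detection is
  deliberately stricter than CRT-style fuzzy matching: it removes a heuristic
  dependency while preserving the downstream contract, which is exact
  full-length spacer matching (zero mismatches, either strand, Ns never
  match). The upstream protocol's spacer E-value cutoff (≤ 1e−10) is subsumed
  by exact matching of ≥ 20-nt spacers.
* **Prophage containment.** Each curated prophage links to the bin of its
  parent scaffold; unbinned parents are flagged. A parent in two bins is a
  binning-integrity error.
* **Shared content.** A merged alignment with ≥ 2,500 nt aligned, identity
  ≥ 0.70, and raw score ≥ 50 links virus to bin. The raw +1/−2 score stands
  in for a BLAST bit score at the same numeric threshold; the E-value clause
  of the source protocol is dropped as redundant — any ≥ 2.5 kb, ≥ 70% hit
  has an astronomically small E-value, so length and identity are the binding
  constraints. Prophages are excluded from this scan (their containment is
  already stronger evidence of the same relationship).

All evidence rows are emitted separately; reconciling multi-evidence
conflicts is left to the user.

## Indicator COGs and AMGs

Group assignment is an explicit analysis input, not an inference. The
default design labels the top **two** layers of each core "surface" (4 vs 7
samples). With only one surface layer per core (2 vs 9), the smallest
attainable exact two-sided rank-sum p is 2/55 ≈ 0.036, which cannot survive
BH correction at q < 0.05 in any family with more indicators than tests —
the two-layer surface group (minimum p = 2/330 ≈ 0.0061) is the smallest
grouping at which BH-corrected indicator calling is possible at all at this
sample size, and it matches the visual surface/deep split of stratified
cores.

The test is the unpaired two-sample Wilcoxon rank-sum, exact by complete
enumeration of the C(n, n₁) group assignments with mid-ranks for ties
(two-sided via deviation from the tie-invariant mean n₁(n+1)/2); the exact
path is used whenever C(n, n₁) ≤ 100,000 — far beyond the 11-sample design —
and the tie-corrected normal approximation beyond that. BH runs over all
testable COGs in one family; all-zero COGs are untestable and excluded from
the family. q < α (default 0.05) defines indicators; direction is the group
with the larger mean. A "99% confidence interval" side-condition mentioned in
the source protocol is ambiguous and not implemented as a separate filter.

The AMG report lists every curated viral scaffold with ≥ 1 COG0175 gene
(PAPS reductase; assimilatory sulfate reduction), its per-layer normalized
coverage at scaffold and gene level, the surface/deep rank-sum p, and
whether a virus-specific gene occurs both up- and downstream of the AMG.

## Community statistics

Bray–Curtis on community profiles (vOTU-level viral coverage; prokaryotic
OTU relative abundance), Euclidean on per-parameter z-scores (sample sd,
n−1; constant parameters dropped with a warning). PCoA is classical scaling:
double-centred −d²/2, eigendecomposition, axes for positive eigenvalues,
negative eigenvalues reported but excluded from the proportion-explained
denominator. ANOSIM R = (mean between-group rank − mean within-group rank) /
(M/2); PERMANOVA uses Anderson's partition (SS_total = Σd²/n; R² = 1 −
SS_within/SS_total; F with g−1 and n−g df). Mantel r is the Pearson
correlation over the n(n−1)/2 pairs with joint row/column permutation of the
second matrix.

Sampled permutation p-values use the add-one convention, p = (1 + #{stat* ≥
stat}) / (1 + permutations), with a seeded generator (default 999
permutations) — p is never 0. Every test also has an exhaustive mode
enumerating all distinct relabellings, used as its own oracle at n ≤ 6.
ANOSIM produces R, not R²; because between-core separation is sometimes
reported under an "R²" label in the literature, the pipeline reports ANOSIM
R and PERMANOVA R² side by side rather than guessing. The indicator-COG
heatmap helper (average linkage on Euclidean distances of log-transformed,
row-z-scored profiles) is a plotting convenience and non-inferential.

## Synthetic community generator

The generator emulates the reference study design — 11 samples in two cores
(6 + 5 depth layers) — at desk scale: 10 host genome bins × 2 scaffolds of
12 kb, 24 free viral ancestors (4 of them seeding multi-member vOTUs of
sizes 3/3/2/2 at 98% within-cluster pairwise identity), 6 prophages embedded
in host scaffolds, 3 decoy microbial scaffolds with detector calls, ~300
prokaryotic OTUs, and library sizes of 0.8–1.3 M reads. These sizes keep a
full pipeline run under ~10 s; they are deliberately one to two orders of
magnitude below a real survey's catalogue.

Planted structure (defaults are the study conditions where the study states
them, otherwise fixed once at field-realistic values):

* **Geochemistry.** pH 2.1→6.8 (core A) and 2.3→6.9 (core B) monotone with
  depth; EC decreasing; TOC/TP increasing; Fe²⁺/TFe rising ~0.08→0.9 and
  SO₄/TS falling ~0.85→0.15 (the oxidative→reductive transition); heavy
  metals at mine-tailings magnitudes with small noise.
* **Prokaryotes.** Euryarchaeota exactly 67% / 80% of the two top layers,
  decaying as (1−t)^1.5 with depth fraction t; archaeal fraction > 0.5 at
  the surface and < 0.2 at depth; bacterial phyla (Proteobacteria,
  Nitrospirae, Firmicutes dominant at depth) scaled into the remainder;
  per-OTU activation depths give monotone richness; counts are multinomial
  draws at 43–135 k reads per sample.
* **Viruses.** Classes: neutral (null-COG carriers), surface-step and
  deep-step indicators (8× group-wise effect between the surface and deep
  analysis groups), COG0175 carriers (> 10 kb, hallmark-flanked AMG, 8×
  deep-enriched), and depth-niche viruses whose evenly spaced activation
  depths create the vOTU richness gradient. A per-taxon log-normal core-B
  multiplier (sd 0.6) plants consistent between-core compositional
  differences in viruses, prophages, and OTUs.
* **Prophages.** The summed prophage share of the viral community is q(pH) =
  clip(0.55 − 0.075·pH + ε, 0.02, 0.9) with ε ~ N(0, 0.08); prophage
  coverage is allocated to make the realized share equal q exactly, so the
  planted affine-in-pH (negative-slope) relation survives the pipeline. The
  slope and noise are not stated by any source and were fixed once so that
  sign recovery is robust at n = 11 (expected r ≈ −0.8); they are otherwise
  arbitrary.
* **Sequences.** i.i.d. per-site substitutions, uniform over the three
  alternative bases, no indels — identity and alignment fraction stay
  analytically controllable. The per-copy rate for a target pairwise
  identity t solves (1−s)² + s²/3 = t. CRISPR spacers are copied verbatim
  (or reverse-complemented) from target viruses into arrays of ≥ 3 exact
  30-nt repeats; decoy spacers carry one central mismatch. Planted
  shared-content regions are 3 kb at ~95% identity. Link-target viruses are
  vOTU singletons so ground-truth link sets stay exact (a cluster co-member
  of a target would legitimately also match).
* **Coverage → counts.** Planted normalized coverage is converted to
  mapped-nucleotide counts by inverting the normalization formula per
  library (coverage × length × reads / mean reads, rounded), so the pipeline
  re-derives the planted values up to rounding. One root seed feeds
  fixed-label child streams per subsystem; adding a feature never perturbs
  existing draws, and identical seeds give byte-identical bundles.

**What the synthetic tests show — and do not.** Passing tests demonstrate
that the implementation recovers *planted* structure exactly under a clean
substitution-only sequence model with step-like effect profiles and
log-normal noise. Real data differ in ways the generator deliberately omits:
indels and chimeric assembly, annotation noise and multi-database conflicts,
fuzzy CRISPR repeats, uneven mapping, compositional coupling between viral
and host abundances, and effect sizes far below 8×. Correlations on the
synthetic bundle (e.g. richness coupling r ≈ 0.96) are therefore cleaner
than the field values (r ≈ 0.65); the generator validates correctness of the
machinery, not field-scale statistical power.

## Degenerate inputs and numerical conventions

Empty detector-call sets produce an empty catalogue, headered empty output
tables, and missing-value statistics (exit 0). All-zero samples are hard
errors for Bray–Curtis; constant parameters are dropped before z-scoring;
zero-variance Pearson inputs are errors. Exact-test ties use mid-ranks;
permutation-test comparisons use a 1e−12 slack so ties with the observed
statistic count as ≥. Internal coordinates are 0-based half-open everywhere;
gene tables on disk are 1-based inclusive with the dialect recorded in the
header. The run manifest echoes the config, seed, input digests, and
per-stage counts.

## Known limitations

* The aligner is gapless between anchors; heavily indel-diverged pairs near
  the 95% threshold would be under-estimated relative to a gapped aligner
  (irrelevant for the substitution-only generator, relevant for real data).
* Greedy centroid clustering depends on the length ordering; graph-based
  single-linkage at the same thresholds can merge chains the greedy rule
  splits.
* CRISPR detection requires exact repeats; degenerate repeats are missed by
  design.
* The bit-score surrogate (+1/−2 raw score) is not a Karlin–Altschul bit
  score; at the 2.5 kb / 70% operating point the length and identity clauses
  dominate, so the distinction does not change link calls.
* Multi-evidence host-link conflicts are reported, not resolved.
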