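"""Generate a synthetic stratified-tailings input bundle and inspect its design.

The generator emulates an 11-sample, two-core sulfidic mine-tailings study:
pH rises from ~2 (oxidized surface) to ~7 (unaltered deep layers), archaea
dominate the surface prokaryotic community, and viral/prokaryotic richness
increase with depth. Everything planted is recorded in the ground truth.
"""

from tailvirkit import SimConfig, simulate_bundle

bundle, truth = simulate_bundle(SimConfig(rng_seed=0), outdir="scratch/bundle")

t = bundle.samples.table
print(t[["core", "depth_cm", "pH", "Fe2_TFe", "SO4_TS"]].round(2))
print(f"\n{len(bundle.scaffolds)} scaffolds, {len(bundle.genes)} genes, "
      f"{len(truth.planted_viral_ids)} planted viral sequences "
      f"({len(truth.planted_prophage_ids)} prophages, "
      f"{len(truth.planted_amg_ids)} ASR-gene carriers)")
print("planted virus-host spacer links:", sorted(truth.planted_spacer_links))
# pH and the redox ratios (Fe2+/TFe up, SO4/TS down) track the oxidative ->
# reductive transition with depth; the bundle on disk under scratch/bundle/
# holds FASTA + TSV inputs that the pipeline (and the CLI) consume.
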