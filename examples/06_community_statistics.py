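"""Community-ecology statistics tying viruses, prokaryotes, and geochemistry.

Bray-Curtis dissimilarities over vOTU (and prokaryotic OTU) profiles,
Euclidean distances on z-scored geochemistry, PCoA ordination, and the
permutation tests: ANOSIM (rank-based R), PERMANOVA (pseudo-F, R^2), and
Mantel correlations between the distance matrices.
"""

import pandas as pd

from tailvirkit import (PipelineConfig, SimConfig, anosim, bray_curtis, euclidean,
                        mantel, pcoa, permanova, run_all, simulate_bundle)

bundle, _ = simulate_bundle(SimConfig(rng_seed=0))
res = run_all(bundle, PipelineConfig(rng_seed=0), seed=0)

d_viral = res.distances["viral_bray_curtis"]
ord_v = pcoa(d_viral)
print("viral PCoA, proportion explained by first two axes:",
      [round(float(p), 3) for p in ord_v.proportion_explained[:2]])

groups = res.groups
r, p = anosim(d_viral, groups, permutations=999, seed=0)
f, r2, pf = permanova(d_viral, groups, permutations=999, seed=0)
print(f"surface vs deep: ANOSIM R = {r:.2f} (p = {p:.3f}); "
      f"PERMANOVA R2 = {r2:.2f} (p = {pf:.3f})")

cores = bundle.samples.table["core"]
r, p = anosim(d_viral, cores, permutations=999, seed=0)
print(f"core A vs core B: ANOSIM R = {r:.2f} (p = {p:.3f})")

mr, mp = mantel(d_viral, res.distances["prok_bray_curtis"], 999, seed=0)
print(f"viral ~ prokaryotic communities: Mantel r = {mr:.2f} (p = {mp:.3f})")
mr, mp = mantel(d_viral, res.distances["geochem_euclidean"], 999, seed=0)
print(f"viral ~ geochemistry:            Mantel r = {mr:.2f} (p = {mp:.3f})")
# depth structures everything: samples separate by layer group in every
# matrix, and the viral community tracks both its hosts and the chemistry.
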