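"""PCoA + PERMANOVA on the organismal distance, PCA on the functional
profile, and Procrustes concordance of the two views.

The PERMANOVA pseudo-F measures how much of the squared-distance variance
lies between groups; its p-value comes from label permutations.  The
Procrustes Monte-Carlo p tests whether the taxon-based and function-based
ordinations agree beyond chance.
"""

from crossfmt import (SimulationConfig, generate_paired_study,
                      pairwise_distances, pca, pcoa, permanova, procrustes_mc)

bundle = generate_paired_study(SimulationConfig(seed=1))

dm = pairwise_distances(bundle.donor_otu, "phylo", tree=bundle.tree)
ordination = pcoa(dm)
print("PCoA proportion explained (first 2 axes):",
      [round(float(p), 3) for p in ordination.proportion_explained[:2]])

res = permanova(dm, bundle.donor_metadata["group"], n_permutations=999, seed=0)
print(f"PERMANOVA (donor, H vs M): F = {res.F:.2f}, p = {res.p:.3f}")

ko_ord = pca(bundle.donor_ko)
m2, p = procrustes_mc(ordination, ko_ord, n_axes=2, n_permutations=999, seed=0)
print(f"Procrustes taxon-vs-function concordance: M2 = {m2:.3f}, p = {p:.4f}")
print("(small M2 / small p: the two molecular views tell the same story)")
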