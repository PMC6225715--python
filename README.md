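# crossfmt

Cross-host microbiome analysis for fecal microbiota transplantation (FMT)
studies, built around the cow-to-mouse mastitis transfer design: donor
animals in a healthy group (H) and a diseased group (M), and germ-free
recipients inoculated from each donor group.  The package answers the
questions such a study asks of its OTU and KO tables:

* how different are the H and M communities, organismally and
  functionally? (phylogeny-weighted beta diversity + PERMANOVA,
  cosine distance on KO profiles, PCoA/PCA, Procrustes concordance)
* which taxa and gene families mark the disease? (per-feature Wilcoxon
  rank-sum tests with Benjamini–Hochberg correction)
* which pathways do the marker genes aggregate into? (reporter-score
  enrichment)
* which taxa drive which functions? (Spearman co-occurrence networks)
* what survives the transplantation, and is the health–disease divergence
  *amplified* in the recipient? (rank-level sharing, direction-concordant
  markers, and the amplification fold)

A synthetic paired-study generator with planted ground truth makes every
stage testable end to end without external data.

## The statistics at the core

**Phylogeny-weighted similarity.** For two relative-abundance profiles
*a*, *b* on the leaves of a rooted tree, a post-order pass matches
abundance as low in the tree as possible: at each node *v* the matched
mass earns weight `w(v) = max(0, 1 − h_v/H)` (node height over tree
height; an exponential decay `w = e^{−λh}` is available), and unmatched
mass propagates upward.  The similarity S ∈ [0, 1] equals
`Σ_i min(a_i, b_i)` (i.e. 1 − Bray–Curtis) on star trees, which serves as
an exact test oracle; the distance is `1 − S`.

**PERMANOVA.** Pseudo-F from squared distances,
`F = (SS_B/(a−1)) / (SS_W/(N−a))` with
`SS_T = Σ_{i<j} d²_ij / N`, p-value by label permutation
(`p = (#{F* ≥ F} + 1)/(n+1)`) or exhaustive enumeration for small designs.

**Reporter score.** Each tested KO contributes `z = Φ⁻¹(1 − p)`; a
pathway with *k* tested KOs scores `Z = Σz/√k`, background-normalized
against random size-*k* KO sets; `Z_adj > 1.6` (the 90% normal quantile
at one decimal) flags a pathway, and it is called "up" only if the number
of significantly up KOs is at least 10% larger than the down count.

**Amplification fold.** `fold = d̄_recipient(H,M) / d̄_donor(H,M)` where
`d̄` is the mean community distance over all between-group sample pairs.
On the published mean distances this yields 0.312/0.104 = 3.0 (OTUs) and
0.389/0.017 ≈ 22.9 → "23-fold" (KOs).

## Worked example

```python
from crossfmt import (SimulationConfig, generate_paired_study,
                      pairwise_distances, permanova, find_markers,
                      amplification_report)

bundle = generate_paired_study(SimulationConfig(seed=1))
dm = pairwise_distances(bundle.donor_otu, "phylo", tree=bundle.tree)
res = permanova(dm, bundle.donor_metadata["group"], n_permutations=999, seed=0)
print(f"F = {res.F:.2f}, p = {res.p:.3f}")

dm_r = pairwise_distances(bundle.recipient_otu, "phylo", tree=bundle.tree)
rep = amplification_report(dm, bundle.donor_metadata,
                           dm_r, bundle.recipient_metadata)
print(f"{rep.donor_mean_between:.3f} -> {rep.recipient_mean_between:.3f}, "
      f"fold = {rep.fold:.2f}")
```

prints

```
F = 72.24, p = 0.001
0.105 -> 0.431, fold = 4.08
```

meaning: the planted disease effect separates the donor groups far beyond
the permutation null (F = 72.2 at the smallest attainable p), and the
recipient's between-group distance is ~4× the donor's on this one seed
(the 20-seed average is ≈ 3.3 for a true planted amplification of 3).
The `examples/` directory has one short script per capability
(simulation, diversity, ordination/PERMANOVA, markers + enrichment,
networks, cross-host statistics); each prints the numbers it computes and
a line on what they mean.  A thin CLI mirrors the library:
`crossfmt simulate|alpha|beta|ordinate|permanova|diff|enrich|network|crosshost|run-all`.

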