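# Methods

## Study design the package models

A paired cross-host FMT design: donor animals split into a healthy group
H and a diseased group M (12 per group by default), and germ-free
recipient animals inoculated per donor group (optionally a third
recipient group P receiving the diseased inoculum plus an intervention).
Inputs are an OTU count table with a rooted phylogeny, a KO relative
abundance table, sample metadata (group, host), a KO→pathway map and an
OTU taxonomy.  The pipeline starts from these tables; read processing,
OTU picking and functional annotation are upstream of it.

## Phylogeny-weighted beta diversity

The organismal distance is a phylogeny-aware generalization of
Bray–Curtis.  In a post-order pass over the rooted tree, abundance shared
by two relative profiles is matched as shallowly as possible: mass
matched at a leaf counts with weight 1; mass that can only be matched at
an ancestor *v* counts with weight `w(v)`; unmatched mass propagates to
the parent.  The default weight is linear in node height,
`w(v) = max(0, 1 − h_v/H)` with `h_v` the longest path from *v* down to a
leaf and `H` the tree height, so the root has weight 0.  Properties that
motivated this choice:

* S ∈ [0, 1]; S = 1 iff the profiles are identical (all mass matched at
  leaves); mass is conserved (matched + root residual = total).
* On a star tree every leaf has weight 1 and the root 0, so
  S = Σ min(aᵢ, bᵢ) exactly — Bray–Curtis similarity.  This limit is the
  package's exact oracle and is asserted to 1e-10 in the tests.
* Matches at deep ancestors are penalized, which is the stated intent of
  weighted phylogenetic community comparisons of this family.

An exponential decay `w(v) = e^{−λh_v}` (λ default 1) ships as an
option.  Both are this package's own concrete definitions; no fidelity
to any published binary is claimed.  Functional (KO) profiles are
compared with cosine distance.  Samples are relative-normalized before
either distance.

## Ordination and tests

PCoA Gower-centers `−d²/2` and eigendecomposes; negative eigenvalues
(semi-metric inputs) are reported in the result but excluded from the
coordinates and from the proportion-explained denominator.  PCA is the
centered, unscaled SVD of the KO table (a `log10(x + pseudocount)`
transform is deliberately not applied by default; relative abundances go
in as they are).  PERMANOVA is one-way (the group factor, matching every
reported comparison), with pseudo-F computed from squared distances and
a seeded permutation p-value; `n_permutations="exact"` enumerates all
distinct relabelings (used for designs up to ~10 samples).  The
permutation p uses the (x+1)/(n+1) convention, so p ≥ 1/(n+1).
Procrustes concordance scales both 2-D configurations to unit trace,
minimizes the residual M² over rotation/translation/scaling
(scipy's procrustes), and permutes the rows of one configuration for the
Monte-Carlo p.

## Marker discovery

Per-feature two-group Wilcoxon rank-sum tests on relative abundances
(raw counts optional), after an occurrence filter keeping features
present in more than five samples (`min_occurrence = 6` — "more than
five" read strictly).  The exact null distribution is used for pooled
n ≤ 12 without ties; otherwise the tie-corrected normal approximation
with continuity correction.  BH adjustment runs over the tested features
of each table.  Thresholds ship as profiles mirroring the study's
choices: `paper-otu` q < 0.01, `paper-ko` p < 0.05 unadjusted,
`paper-network` one-tail q < 0.01, `default` q < 0.1.  "One-tail" mode
takes the smaller of the two one-sided p-values, i.e. the tail of the
observed rank direction.  Effects are reported as differences of group
mean relative abundances and as log2 ratios with pseudocount 1e-6.

## Reporter-score enrichment

Two-sided KO p-values are transformed to `z = Φ⁻¹(1 − p)` (clamped to
[1e-15, 1−1e-15]); a pathway with k tested member KOs scores
`Z_raw = Σz/√k`; the background correction draws 1000 random size-k
subsets of the full tested-KO z pool and standardizes
(`Z_adj = (Z_raw − μ)/σ`).  Significance: `Z_adj > 1.6`, the 90%
two-sided normal quantile (1.645) at one-decimal precision.  Up/down KO
counts come from one-sided rank-sum tests at α = 0.05; the pathway
direction applies the multiplicative 10% rule `n_up ≥ 1.1·n_down`
(exact real comparison, no rounding) and is "mixed" otherwise.  The
subset-sampling background and the use of two-sided p for Z (one-sided
only for direction counts) are this package's concrete instantiation of
the reporter-feature idea; under a global null the flag rate is ≈ the
one-sided normal tail at 1.6 (≈ 5.5%), verified in the tests.

## Co-occurrence networks

All differential OTU × differential KO pairs (same-kind pairs optional)
are scored by Spearman correlation across shared samples; edges require
|ρ| > 0.8 and BH q < 0.01 over all tested pairs.  Plain Spearman + BH is
used rather than a resampling-based correlation screen; the magnitude
reading of the ρ threshold follows the presence of negative (dashed)
edges in the study's network figures.  Constant features are skipped
with a warning.  Exports: GraphML and a plain edge TSV.

## Cross-host statistics

* Mean between-group distance: the arithmetic mean of d(i, j) over all
  pairs with i in one group and j in the other — the only reading that
  produces a single scalar per host; within-group pairs are excluded.
* Amplification fold: recipient over donor mean between-group distance.
  Full precision is kept; "3-fold"/"23-fold" style integers are a
  formatting layer (round-half-up).
* Rank-level sharing: the fraction of a recipient group's community
  attributable to taxa present in the paired donor group, at OTU, genus
  or family rank; abundance-weighted by default with a count-based
  option (the percentage basis of such figures is typically not printed,
  so both are provided and neither is claimed to reproduce any published
  value).  Unclassified ranks never match anything, including each
  other.
* Concordant markers: features (KOs by id; OTUs by rank-level taxon)
  significant in both hosts with the same direction of change; a taxon
  whose member markers disagree in sign within one host is dropped.

## Synthetic data generator

The generator emulates the paired design so that every downstream stage
has planted ground truth:

* **Tree**: random pairwise joins, exponential branch lengths (scale
  0.1), leaves `OTU_1..n`.  Taxonomy derives from clades: phyla are the
  two root subtrees, families/genera the maximal clades below 50%/25% of
  tree height, so ranks nest consistently by construction.
* **Baseline composition**: lognormal (σ = 1) relative abundance
  profile over 150 OTUs.
* **Planted markers**: 20 OTUs, half enriched in M from one root clade,
  half depleted from the other — disease shifts in real dysbiosis data
  are phylum-coherent, and this also keeps the phylogeny-weighted
  distance responsive to signal rather than to leaf-level sampling
  noise.  Planted OTUs are drawn from the abundant half of their clade:
  a rank-sum test at n = 12 has adequate power only for taxa whose
  counts rise above the sampling noise, and published marker sets are
  accordingly made of detectable taxa.
* **Counts**: per sample, Dirichlet–multinomial around the group mean
  composition with 10,000 reads (the order of a typical amplicon
  library).  `base_concentration` (default 50) is the per-taxon
  Dirichlet mass at average abundance, i.e. α = 50 · n_otus · p; this
  gives within-group noise compatible with recovering a log2 effect of
  1.5 at n = 12 — the generator's stated design point.  (Read as a
  *total* Dirichlet mass of 50 the model is so overdispersed that no
  rank test at this design size retains power; see the limitations.)
* **Donor effect**: group M multiplies planted OTUs by `2^(±1.5)` and
  renormalizes.
* **Recipient**: re-seeded from the empirical donor group mean
  composition (pooled-inoculum default; a per-recipient donor draw is
  available), with a per-group engraftment dropout (default 0.1)
  discarding random background OTUs, and the planted effect raised to
  `log2_effect × amplification` (default amplification 3).  A
  `concordant_fraction` knob flips the recipient sign of a subset of
  planted OTUs to emulate cross-host marker discordance.
* **KO layer**: a nonnegative OTU × KO gene-content matrix (each KO
  carried by ~10 random OTUs, lognormal weights); KO profile =
  relative OTU profile × gene content, multiplied by mean-one lognormal
  noise (CV 0.2), renormalized.  Four planted pathways (2 up, 2 down)
  have their member KOs additionally coupled to the planted OTUs of the
  matching sign so KO-level shifts aggregate at the pathway level.
  Group P, when generated, keeps M's organismal composition but pulls
  its planted-pathway KO values toward the H mean (functional recovery
  without structural recovery).

All randomness flows from one seed through `numpy.random.SeedSequence`;
bundles are bit-reproducible.

### What the generator does and does not emulate

It reproduces the design's group structure, compositional count noise,
phylum-coherent differential structure, taxon-driven functional shifts
and donor→recipient amplification.  It does **not** emulate:
recipient-novel (environmentally acquired) taxa — so recipient→donor
sharing fractions are 1 by construction and the sharing statistic is
exercised by dedicated unit fixtures instead; true zero-inflation beyond
what the Dirichlet–multinomial produces; phylogenetic signal in the
gene-content matrix beyond the planted pathways; and any wet-lab
quantity (symptoms, cytokines, cell counts).  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under a
plausible generative model, not performance on real sequencing data.

## Numerical choices and degenerate inputs

* Similarities are clipped to [0, 1] before distances; relative rows are
  validated to 1e-9, and distance functions re-check to 1e-6.
* PCoA/PCA keep eigenvalues above 1e-10 of the leading one; an
  all-degenerate input yields one all-zero axis.
* PERMANOVA with zero within-group variance reports F = ∞ (signal, no
  noise) or 0 (no variance at all, p = 1).
* The permutation comparisons use a 1e-12 slack so that ties in F count
  as "at least as extreme".
* BH on an empty vector returns an empty vector; enrichment of an empty
  KO frame returns an empty table.
* `background_correct` refuses a zero-variance pool (degenerate
  background) and pathways larger than the pool.

## Problem sizes used by the test and acceptance runs

Unit tests use scaled-down bundles (60 OTUs, 8 samples/group);
calibration and recovery checks run the default design (150 OTUs,
12 samples/group) over 50 null seeds and 20 effect seeds; exhaustive
PERMANOVA instances go up to 10 samples; determinism is checked by
hashing two complete pipeline runs at the default design.  These sizes
were chosen so the whole battery completes in a few minutes on one CPU
while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* The phylogeny-weighted distance is a defined-here variant; numbers are
  not comparable to other implementations of phylogeny-aware distances
  (including UniFrac, which is out of scope).
* KO-level amplification folds on synthetic bundles are compressed
  relative to the organismal fold (the gene-content mixture averages
  across OTUs), so only the organismal fold is compared against the
  planted amplification.
* Group sharing and concordance depend on the taxonomy's resolution;
  with the clade-derived synthetic taxonomy, genus-level results are
  optimistic relative to real annotation pipelines.
* The engraftment dropout adds between-group distance in the recipient
  even at amplification 1, so estimated folds have a positive bias of
  roughly +0.3 at the default settings.
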