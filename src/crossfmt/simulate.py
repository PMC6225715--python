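"""Synthetic paired donor/recipient FMT studies with planted differential structure.

The generator emulates the design of a cow-to-mouse transplantation study:
two host generations (donor cows, recipient germ-free mice), groups H
(healthy) and M (mastitis) of 12 samples each (optionally a
probiotic-treated group P in the recipient), group-differential OTUs of
both signs, KO profiles induced from OTUs through a gene-content matrix,
and a tunable amplification of the between-group divergence from donor to
recipient.

Count model: per-sample compositions are Dirichlet draws around the group
mean composition (``base_concentration`` controls within-group dispersion)
followed by a multinomial read draw (``depth`` reads per sample, the order
of magnitude of a typical amplicon library).  Planted "+" OTUs are drawn
from one deep clade of the random tree and "-" OTUs from the other, so
that disease shifts are phylum-coherent, as in real dysbiosis signatures.
Recipient communities are re-seeded from the (pooled) donor group mean
composition; a per-group engraftment dropout removes random background
OTUs, mimicking incomplete transfer.  The recipient's planted log2 effect
is ``log2_effect * amplification``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from . import io as cio
from .tables import FeatureTable, PathwayMap, TaxonomyMap, normalize_relative


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic paired study."""

    n_otus: int = 150
    n_kos: int = 400
    n_pathways: int = 20
    samples_per_group: int = 12      # 12 donors per group, as in the study
    base_concentration: float = 50.0  # per-taxon Dirichlet mass at average abundance
    depth: int = 10000                # reads per sample
    n_diff_otus: int = 20
    log2_effect: float = 1.5          # planted donor effect, log2 scale
    amplification: float = 3.0        # recipient effect multiplier
    ko_noise_cv: float = 0.2          # lognormal CV of the OTU->KO mapping
    engraftment_dropout: float = 0.1  # per-group loss of background OTUs
    n_planted_pathways_per_sign: int = 2
    concordant_fraction: float = 1.0  # planted OTUs keeping their sign in recipient
    include_group_p: bool = False
    p_recovery: float = 0.7           # pull of planted KO effects toward H in group P
    pooled_inoculum: bool = True
    branch_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diff_otus > self.n_otus:
            raise ValueError("n_diff_otus cannot exceed n_otus")
        if self.samples_per_group < 3:
            raise ValueError("samples_per_group must be >= 3")
        if self.log2_effect < 0 or self.amplification <= 0:
            raise ValueError("log2_effect must be >= 0 and amplification > 0")
        if not 0 <= self.concordant_fraction <= 1:
            raise ValueError("concordant_fraction must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure (simulated ids only)."""

    otu_signs: dict[str, int]            # +1 enriched in donor M, -1 depleted
    recipient_otu_signs: dict[str, int]  # sign in the recipient (may be flipped)
    pathway_signs: dict[str, int]        # +1 up in M, -1 down in M
    amplification: float


@dataclass
class StudyBundle:
    donor_otu: FeatureTable
    donor_ko: FeatureTable
    donor_metadata: pd.DataFrame
    recipient_otu: FeatureTable
    recipient_ko: FeatureTable
    recipient_metadata: pd.DataFrame
    tree: skbio.TreeNode
    pathway_map: PathwayMap
    taxonomy: TaxonomyMap
    gene_content: pd.DataFrame  # OTU x KO nonnegative weights
    truth: PlantedTruth
    config: SimulationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def generate_tree(n_leaves: int, seed: int, branch_scale: float = 0.1) -> skbio.TreeNode:
    """Random bifurcating rooted tree with exponential branch lengths.

    Leaves are named ``OTU_1 .. OTU_n``; topology by random pairwise joins.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(n_leaves):
        leaf = skbio.TreeNode(name=f"OTU_{i + 1}")
        leaf.length = float(rng.exponential(branch_scale))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(children=[a, b])
        parent.length = float(rng.exponential(branch_scale))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def taxonomy_from_tree(tree: skbio.TreeNode, family_frac: float = 0.5,
                       genus_frac: float = 0.25) -> TaxonomyMap:
    """Derive a consistent 3-rank taxonomy from tree clades.

    Phyla are the root's children; families (genera) are the maximal clades
    whose height is at most ``family_frac`` (``genus_frac``) of the tree
    height, so genera nest inside families by construction.
    """
    heights: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            heights[id(node)] = 0.0
        else:
            heights[id(node)] = max(heights[id(c)] + (c.length or 0.0)
                                    for c in node.children)
    total = max(heights[id(tree)], 1e-12)

    def clades_below(frac: float) -> list[list[str]]:
        out: list[list[str]] = []

        def walk(node):
            if node.is_tip() or heights[id(node)] <= frac * total:
                out.append([t.name for t in node.tips(include_self=True)])
            else:
                for child in node.children:
                    walk(child)

        walk(tree)
        return out

    lineage: dict[str, dict[str, str]] = {}
    for p, child in enumerate(tree.children, start=1):
        for tip in child.tips(include_self=True):
            lineage[tip.name] = {"phylum": f"P{p}"}
    for label, frac in (("family", family_frac), ("genus", genus_frac)):
        for k, clade in enumerate(clades_below(frac), start=1):
            for tip_name in clade:
                lineage[tip_name][label] = f"{label[0].upper()}{k}"
    frame = pd.DataFrame.from_dict(lineage, orient="index")
    frame.index.name = "otu_id"
    return TaxonomyMap(lineages=frame)


# ---------------------------------------------------------------------------
# KO layer
# ---------------------------------------------------------------------------

def otu_to_ko_table(otu_table: FeatureTable, gene_content: pd.DataFrame,
                    noise_cv: float = 0.0, seed: int | None = None) -> FeatureTable:
    """Induce a KO table: relative OTU abundances x gene content, noised, renormalized."""
    if (gene_content.to_numpy() < 0).any():
        raise ValueError("gene content weights must be nonnegative")
    rel = normalize_relative(otu_table)
    aligned = gene_content.loc[rel.feature_ids]
    ko = rel.values() @ aligned.to_numpy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
        ko = ko * np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=ko.shape))
    frame = pd.DataFrame(ko, index=rel.sample_ids, columns=aligned.columns)
    table = FeatureTable(data=frame, kind="ko", normalization="counts")
    return normalize_relative(table)


# ---------------------------------------------------------------------------
# paired study
# ---------------------------------------------------------------------------

def _sample_counts(rng: np.random.Generator, mean: np.ndarray, n_samples: int,
                   concentration: float, depth: int) -> np.ndarray:
    # ``concentration`` is per taxon at average abundance: a taxon at the
    # community-average relative abundance has Dirichlet mass equal to it
    alpha = np.maximum(concentration * mean.size * mean, 1e-8)
    counts = np.empty((n_samples, mean.size), dtype=int)
    for i in range(n_samples):
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depth, p)
    return counts


def _apply_effect(mean: np.ndarray, otu_index: dict[str, int],
                  signs: dict[str, int], log2_effect: float) -> np.ndarray:
    shifted = mean.copy()
    for otu, sign in signs.items():
        shifted[otu_index[otu]] *= 2.0 ** (sign * log2_effect)
    return shifted / shifted.sum()


def generate_paired_study(config: SimulationConfig) -> StudyBundle:
    """Generate one full donor + recipient bundle with planted truth."""
    seeds = np.random.SeedSequence(config.seed).generate_state(10) % (2 ** 31)
    rng = np.random.default_rng(seeds[0])

    tree = generate_tree(config.n_otus, int(seeds[1]), config.branch_scale)
    otus = [f"OTU_{i + 1}" for i in range(config.n_otus)]
    otu_index = {o: i for i, o in enumerate(otus)}
    kos = [f"K{j + 1:05d}" for j in range(config.n_kos)]
    pathways = [f"pw{k + 1:03d}" for k in range(config.n_pathways)]
    taxonomy = taxonomy_from_tree(tree)

    # baseline composition (lognormal abundance profile)
    base = np.exp(rng.normal(0.0, 1.0, size=config.n_otus))
    mean_h = base / base.sum()

    # planted OTUs: "+" from one root clade, "-" from the other
    # (phylum-coherent dysbiosis), preferring the abundant half of each
    # clade — markers are detectable taxa
    clade_tips = [[t.name for t in child.tips(include_self=True)]
                  for child in tree.children]
    clade_tips.sort(key=len, reverse=True)
    n_plus = config.n_diff_otus // 2
    n_minus = config.n_diff_otus - n_plus

    def abundant_first(pool: list[str]) -> list[str]:
        ranked = sorted(pool, key=lambda o: mean_h[otu_index[o]], reverse=True)
        return ranked[:max(len(ranked) // 2, 1)]

    plus_pool = clade_tips[0] if clade_tips else otus
    minus_pool = clade_tips[1] if len(clade_tips) > 1 else otus
    enriched = _pick(rng, abundant_first(plus_pool), n_plus, exclude=set())
    depleted = _pick(rng, abundant_first(minus_pool), n_minus,
                     exclude=set(enriched))
    otu_signs = {**{o: 1 for o in enriched}, **{o: -1 for o in depleted}}

    # recipient signs: a configurable fraction keeps the donor direction
    planted = list(enriched) + list(depleted)
    n_keep = int(round(config.concordant_fraction * len(planted)))
    keep_set = set(rng.choice(planted, size=n_keep, replace=False)) if planted else set()
    recipient_signs = {o: (s if o in keep_set else -s) for o, s in otu_signs.items()}

    # donor group means
    mean_m = _apply_effect(mean_h, otu_index, otu_signs, config.log2_effect)

    n = config.samples_per_group
    donor_counts, donor_ids, donor_meta = [], [], []
    for group, mean in (("H", mean_h), ("M", mean_m)):
        donor_counts.append(_sample_counts(rng, mean, n,
                                           config.base_concentration, config.depth))
        donor_ids += [f"cow_{group}_{i + 1:02d}" for i in range(n)]
        donor_meta += [{"group": group, "host": "cow"}] * n
    donor_otu = FeatureTable(
        pd.DataFrame(np.vstack(donor_counts), index=donor_ids, columns=otus),
        kind="otu", normalization="counts")
    donor_metadata = pd.DataFrame(donor_meta, index=pd.Index(donor_ids, name="sample_id"))

    # recipient seeded from the donor group composition
    donor_rel = normalize_relative(donor_otu).data
    emp = {g: donor_rel.loc[donor_metadata["group"] == g].mean(axis=0).to_numpy()
           for g in ("H", "M")}
    background = [o for o in otus if o not in otu_signs]
    recip_mean = {}
    for group in ("H", "M"):
        mean = emp[group].copy()
        dropped = [o for o in background
                   if rng.random() < config.engraftment_dropout]
        for o in dropped:
            mean[otu_index[o]] = 0.0
        mean = mean / mean.sum()
        if group == "M":
            # residual multiplier so the total recipient effect vs H is
            # log2_effect * amplification with the recipient's own signs
            shifted = mean.copy()
            for o, donor_sign in otu_signs.items():
                exponent = (recipient_signs[o] * config.amplification - donor_sign)
                shifted[otu_index[o]] *= 2.0 ** (exponent * config.log2_effect)
            mean = shifted / shifted.sum()
        recip_mean[group] = mean

    groups = ["H", "M"] + (["P"] if config.include_group_p else [])
    recip_counts, recip_ids, recip_meta = [], [], []
    for group in groups:
        mean = recip_mean["M"] if group == "P" else recip_mean[group]
        if config.pooled_inoculum:
            recip_counts.append(_sample_counts(rng, mean, n,
                                               config.base_concentration,
                                               config.depth))
        else:
            block = np.empty((n, config.n_otus), dtype=int)
            source_group = "M" if group == "P" else group
            donors = donor_rel.loc[donor_metadata["group"] == source_group].to_numpy()
            for i in range(n):
                per_donor = donors[rng.integers(donors.shape[0])].copy()
                mask = mean > 0
                per_donor = np.where(mask, per_donor, 0.0)
                if group in ("M", "P"):
                    for o, donor_sign in otu_signs.items():
                        exponent = (recipient_signs[o] * config.amplification
                                    - donor_sign)
                        per_donor[otu_index[o]] *= 2.0 ** (exponent * config.log2_effect)
                per_donor = per_donor / per_donor.sum()
                block[i] = _sample_counts(rng, per_donor, 1,
                                          config.base_concentration,
                                          config.depth)[0]
            recip_counts.append(block)
        recip_ids += [f"mouse_{group}_{i + 1:02d}" for i in range(n)]
        recip_meta += [{"group": group, "host": "mouse"}] * n
    recipient_otu = FeatureTable(
        pd.DataFrame(np.vstack(recip_counts), index=recip_ids, columns=otus),
        kind="otu", normalization="counts")
    recipient_metadata = pd.DataFrame(recip_meta,
                                      index=pd.Index(recip_ids, name="sample_id"))

    # gene content, pathway map, planted pathways
    gene_content, pathway_map, pathway_signs = _gene_content(
        rng, otus, kos, pathways, enriched, depleted,
        config.n_planted_pathways_per_sign)

    donor_ko = otu_to_ko_table(donor_otu, gene_content, config.ko_noise_cv,
                               seed=int(seeds[2]))
    recipient_ko = otu_to_ko_table(recipient_otu, gene_content, config.ko_noise_cv,
                                   seed=int(seeds[3]))
    if config.include_group_p and config.p_recovery > 0:
        recipient_ko = _pull_group_p(recipient_ko, recipient_metadata,
                                     pathway_map, pathway_signs, config.p_recovery)

    truth = PlantedTruth(otu_signs=otu_signs, recipient_otu_signs=recipient_signs,
                         pathway_signs=pathway_signs,
                         amplification=config.amplification)
    return StudyBundle(donor_otu=donor_otu, donor_ko=donor_ko,
                       donor_metadata=donor_metadata,
                       recipient_otu=recipient_otu, recipient_ko=recipient_ko,
                       recipient_metadata=recipient_metadata,
                       tree=tree, pathway_map=pathway_map, taxonomy=taxonomy,
                       gene_content=gene_content, truth=truth, config=config)


def _pick(rng: np.random.Generator, pool: list[str], k: int,
          exclude: set[str]) -> list[str]:
    pool = [o for o in pool if o not in exclude]
    if len(pool) >= k:
        return list(rng.choice(pool, size=k, replace=False))
    return pool  # degenerate topologies: take what the clade has


def _gene_content(rng, otus, kos, pathways, enriched, depleted, n_per_sign):
    n_otus, n_kos = len(otus), len(kos)
    weights = np.zeros((n_otus, n_kos))
    carriers_per_ko = rng.poisson(8, size=n_kos) + 2
    for j in range(n_kos):
        carriers = rng.choice(n_otus, size=min(carriers_per_ko[j], n_otus),
                              replace=False)
        weights[carriers, j] = rng.lognormal(0.0, 0.5, size=carriers.size)

    # pathway membership: one primary pathway per KO + occasional second
    primary = rng.integers(len(pathways), size=n_kos)
    ko_to_pathways = {kos[j]: {pathways[primary[j]]} for j in range(n_kos)}
    for j in range(n_kos):
        if rng.random() < 0.3:
            ko_to_pathways[kos[j]].add(pathways[int(rng.integers(len(pathways)))])

    # planted pathways: couple their member KOs to planted OTUs so that
    # KO-level differences aggregate at the pathway level
    order = rng.permutation(len(pathways))
    planted_up = [pathways[i] for i in order[:n_per_sign]]
    planted_down = [pathways[i] for i in order[n_per_sign:2 * n_per_sign]]
    pathway_signs = {**{p: 1 for p in planted_up}, **{p: -1 for p in planted_down}}
    otu_index = {o: i for i, o in enumerate(otus)}
    for j in range(n_kos):
        pw = pathways[primary[j]]
        if pw in pathway_signs:
            anchors = enriched if pathway_signs[pw] > 0 else depleted
            idx = [otu_index[o] for o in anchors]
            weights[idx, j] += rng.lognormal(1.2, 0.3, size=len(idx))
    gene_content = pd.DataFrame(weights, index=otus, columns=kos)
    return gene_content, PathwayMap(ko_to_pathways=ko_to_pathways), pathway_signs


def _pull_group_p(recipient_ko, recipient_metadata, pathway_map, pathway_signs,
                  p_recovery):
    """Blend group-P planted-pathway KOs toward the group-H mean (functional recovery)."""
    frame = recipient_ko.data.copy()
    planted_kos = sorted({ko for ko, pws in pathway_map.ko_to_pathways.items()
                          if pws & set(pathway_signs)} & set(frame.columns))
    h_mask = recipient_metadata.loc[frame.index, "group"] == "H"
    p_mask = recipient_metadata.loc[frame.index, "group"] == "P"
    h_mean = frame.loc[h_mask.to_numpy(), planted_kos].mean(axis=0)
    block = frame.loc[p_mask.to_numpy(), planted_kos]
    frame.loc[p_mask.to_numpy(), planted_kos] = (
        (1 - p_recovery) * block + p_recovery * h_mean.to_numpy()[None, :]
    )
    table = FeatureTable(frame, kind="ko", normalization="counts")
    return normalize_relative(table)


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

def write_bundle(bundle: StudyBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cio.write_feature_table(bundle.donor_otu, directory / "donor_otu.tsv")
    cio.write_feature_table(bundle.donor_ko, directory / "donor_ko.tsv")
    cio.write_feature_table(bundle.recipient_otu, directory / "recipient_otu.tsv")
    cio.write_feature_table(bundle.recipient_ko, directory / "recipient_ko.tsv")
    metadata = pd.concat([bundle.donor_metadata, bundle.recipient_metadata])
    cio.write_metadata(metadata, directory / "metadata.tsv")
    cio.write_tree(bundle.tree, directory / "tree.nwk")
    cio.write_pathway_map(bundle.pathway_map, directory / "pathway_map.tsv")
    cio.write_taxonomy(bundle.taxonomy, directory / "taxonomy.tsv")
    bundle.gene_content.rename_axis("otu_id").to_csv(
        directory / "gene_content.tsv", sep="\t")
    truth = {
        "otu_signs": bundle.truth.otu_signs,
        "recipient_otu_signs": bundle.truth.recipient_otu_signs,
        "pathway_signs": bundle.truth.pathway_signs,
        "amplification": bundle.truth.amplification,
    }
    with open(directory / "truth.json", "w") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
    if bundle.config is not None:
        with open(directory / "config.json", "w") as handle:
            json.dump(dataclasses.asdict(bundle.config), handle, indent=1,
                      sort_keys=True)
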