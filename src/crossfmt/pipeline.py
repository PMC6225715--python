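"""Full-study orchestration: simulate/load -> diversity -> ordination ->
markers -> enrichment -> network -> cross-host report.

Every stage writes its outputs under the run directory; the final
:class:`RunReport` (JSON + text) echoes all parameters and headline
numbers (PERMANOVA F/p per host, marker counts, enriched pathways,
amplification folds) so each reported value is traceable to a persisted
intermediate.  One global seed deterministically derives all stage seeds;
a repeated run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as cio
from .alpha import alpha_diversity
from .beta import pairwise_distances, write_distance_matrix
from .crosshost import amplification_report, concordant_markers, shared_features
from .enrichment import enrich, write_pathway_scores
from .markers import PROFILES, find_markers, differential_stats, write_markers
from .multivariate import pca, pcoa, permanova, procrustes_mc, write_ordination
from .network import build_network, export_network
from .simulate import SimulationConfig, StudyBundle, generate_paired_study, write_bundle
from .tables import FeatureTable


@dataclass
class PipelineConfig:
    """One config object driving the whole analysis."""

    output_dir: str = "crossfmt_run"
    seed: int = 0
    #: either a simulation block (default) or a directory of input files
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    weight_mode: str = "linear"
    decay: float = 1.0
    n_permutations: int = 999
    min_occurrence: int = 6
    otu_profile: str = "default"
    ko_profile: str = "paper-ko"
    network_profile: str = "paper-network"
    z_threshold: float = 1.6
    wilcoxon_alpha: float = 0.05
    n_background_draws: int = 1000
    rho_threshold: float = 0.8
    network_q_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            self.simulation = SimulationConfig(seed=self.seed)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.get("simulation")
        if isinstance(sim, dict):
            data["simulation"] = SimulationConfig(**sim)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def validate_inputs(otu_table: FeatureTable, ko_table: FeatureTable | None,
                    tree, metadata: pd.DataFrame, pathway_map=None) -> dict:
    """Cross-check ids between tables, tree, metadata and pathway map.

    Returns ``{"errors": [...], "warnings": [...]}``; errors are fatal for
    the pipeline, warnings are not.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    missing_meta = set(otu_table.sample_ids) - set(metadata.index)
    if missing_meta:
        errors.append(f"samples without metadata: {sorted(missing_meta)}")
    if tree is not None:
        leaves = {tip.name for tip in tree.tips()}
        orphans = sorted(set(otu_table.feature_ids) - leaves)
        if orphans:
            errors.append(f"OTUs absent from tree: {orphans}")
    if ko_table is not None:
        if pathway_map is not None:
            unmapped = sorted(set(ko_table.feature_ids)
                              - set(pathway_map.ko_to_pathways))
            if unmapped:
                warnings_.append(f"KOs absent from pathway map: {unmapped}")
        extra_meta = set(metadata.index) - set(otu_table.sample_ids) \
            - set(ko_table.sample_ids)
        if extra_meta:
            warnings_.append(f"metadata samples without any table: {sorted(extra_meta)}")
    return {"errors": errors, "warnings": warnings_}


def _load_bundle(input_dir: str) -> StudyBundle:
    from .simulate import PlantedTruth

    directory = Path(input_dir)
    metadata = cio.read_metadata(directory / "metadata.tsv")
    donor_ids = metadata.index[metadata["host"] == "cow"]
    recip_ids = metadata.index[metadata["host"] == "mouse"]
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        with open(truth_path) as handle:
            raw = json.load(handle)
        truth = PlantedTruth(
            otu_signs={k: int(v) for k, v in raw["otu_signs"].items()},
            recipient_otu_signs={k: int(v)
                                 for k, v in raw["recipient_otu_signs"].items()},
            pathway_signs={k: int(v) for k, v in raw["pathway_signs"].items()},
            amplification=float(raw["amplification"]))
    gene_content_path = directory / "gene_content.tsv"
    gene_content = (pd.read_csv(gene_content_path, sep="\t", index_col=0)
                    if gene_content_path.exists() else None)
    taxonomy_path = directory / "taxonomy.tsv"
    taxonomy = cio.read_taxonomy(taxonomy_path) if taxonomy_path.exists() else None
    return StudyBundle(
        donor_otu=cio.read_feature_table(directory / "donor_otu.tsv", kind="otu"),
        donor_ko=cio.read_feature_table(directory / "donor_ko.tsv", kind="ko",
                                        normalization="relative"),
        donor_metadata=metadata.loc[donor_ids],
        recipient_otu=cio.read_feature_table(directory / "recipient_otu.tsv",
                                             kind="otu"),
        recipient_ko=cio.read_feature_table(directory / "recipient_ko.tsv",
                                            kind="ko", normalization="relative"),
        recipient_metadata=metadata.loc[recip_ids],
        tree=cio.read_tree(directory / "tree.nwk"),
        pathway_map=cio.read_pathway_map(directory / "pathway_map.tsv"),
        taxonomy=taxonomy, gene_content=gene_content, truth=truth, config=None)


def run_full(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also persisted as JSON + text)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = np.random.SeedSequence(config.seed).generate_state(16) % (2 ** 31)
    report: dict = {"version": __version__, "config": config.to_dict(),
                    "stages": {}}

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        if config.input_dir is not None:
            bundle = _load_bundle(config.input_dir)
        else:
            bundle = generate_paired_study(config.simulation)
            write_bundle(bundle, out / "bundle")
        all_warnings: list[str] = []
        for otu, ko, meta in ((bundle.donor_otu, bundle.donor_ko,
                               bundle.donor_metadata),
                              (bundle.recipient_otu, bundle.recipient_ko,
                               bundle.recipient_metadata)):
            validation = validate_inputs(otu, ko, bundle.tree, meta,
                                         bundle.pathway_map)
            if validation["errors"]:
                raise ValueError("; ".join(validation["errors"]))
            all_warnings += validation["warnings"]
        report["stages"][stage] = {"status": "ok", "warnings": all_warnings}
    except Exception as exc:
        _fail(report, out, stage, exc)

    hosts = {"donor": (bundle.donor_otu, bundle.donor_ko, bundle.donor_metadata),
             "recipient": (bundle.recipient_otu, bundle.recipient_ko,
                           bundle.recipient_metadata)}

    # ---- alpha -----------------------------------------------------------
    stage = "alpha"
    try:
        for host, (otu, _ko, _meta) in hosts.items():
            alpha_diversity(otu).to_csv(out / f"alpha_{host}.tsv", sep="\t")
        report["stages"][stage] = {"status": "ok"}
    except Exception as exc:
        _fail(report, out, stage, exc)

    # ---- beta ------------------------------------------------------------
    stage = "beta"
    dms = {}
    try:
        if bundle.tree is None:
            raise ValueError("phylogenetic distance requested but no tree provided")
        for host, (otu, ko, _meta) in hosts.items():
            dms[host, "otu"] = pairwise_distances(otu, "phylo", tree=bundle.tree,
                                                  weight_mode=config.weight_mode,
                                                  decay=config.decay)
            dms[host, "ko"] = pairwise_distances(ko, "cosine")
            write_distance_matrix(dms[host, "otu"], out / f"beta_{host}_otu.tsv")
            write_distance_matrix(dms[host, "ko"], out / f"beta_{host}_ko.tsv")
        report["stages"][stage] = {"status": "ok"}
    except Exception as exc:
        _fail(report, out, stage, exc)

    # ---- ordination + permanova + procrustes ------------------------------
    stage = "ordination"
    try:
        headline = {}
        seed_iter = iter(stage_seeds.tolist())
        ordinations = {}
        for host, (otu, ko, meta) in hosts.items():
            groups = meta.loc[meta["group"].isin(["H", "M"])].index
            ord_otu = pcoa(dms[host, "otu"])
            ord_ko = pca(ko)
            ordinations[host] = (ord_otu, ord_ko)
            write_ordination(ord_otu, out / f"pcoa_{host}_otu.tsv")
            write_ordination(ord_ko, out / f"pca_{host}_ko.tsv")
            for kind in ("otu", "ko"):
                dm_hm = dms[host, kind].filter(groups)
                res = permanova(dm_hm, meta["group"],
                                n_permutations=config.n_permutations,
                                seed=int(next(seed_iter)))
                headline[f"permanova_{host}_{kind}"] = {
                    "F": res.F, "p": res.p,
                    "n_permutations": res.n_permutations}
            m2, p_proc = procrustes_mc(ord_otu, ord_ko, n_axes=2,
                                       n_permutations=config.n_permutations,
                                       seed=int(next(seed_iter)))
            headline[f"procrustes_{host}"] = {"m2": m2, "p": p_proc}
        report["stages"][stage] = {"status": "ok", **headline}
    except Exception as exc:
        _fail(report, out, stage, exc)

    # ---- markers ---------------------------------------------------------
    stage = "markers"
    try:
        marker_frames = {}
        stats_frames = {}
        for host, (otu, ko, meta) in hosts.items():
            for kind, table, profile in (("otu", otu, config.otu_profile),
                                         ("ko", ko, config.ko_profile)):
                stats_frames[host, kind] = differential_stats(
                    table, meta, min_occurrence=config.min_occurrence,
                    mode=PROFILES[profile].mode)
                marker_frames[host, kind] = find_markers(
                    table, meta, min_occurrence=config.min_occurrence,
                    profile=profile)
                write_markers(marker_frames[host, kind],
                              out / f"markers_{host}_{kind}.tsv")
        report["stages"][stage] = {
            "status": "ok",
            **{f"n_markers_{host}_{kind}": int(len(frame))
               for (host, kind), frame in marker_frames.items()},
        }
    except Exception as exc:
        _fail(report, out, stage, exc)

    # ---- enrichment ------------------------------------------------------
    stage = "enrichment"
    try:
        enriched = {}
        for host in hosts:
            scores = enrich(stats_frames[host, "ko"], bundle.pathway_map,
                            z_threshold=config.z_threshold,
                            wilcoxon_alpha=config.wilcoxon_alpha,
                            n_draws=config.n_background_draws,
                            seed=int(next(seed_iter)))
            enriched[host] = scores
            write_pathway_scores(scores, out / f"pathways_{host}.tsv")
        report["stages"][stage] = {
            "status": "ok",
            **{f"n_enriched_{host}": int(scores["significant"].sum())
               for host, scores in enriched.items()},
        }
    except Exception as exc:
        _fail(report, out, stage, exc)

    # ---- network ---------------------------------------------------------
    stage = "network"
    try:
        networks = {}
        for host, (otu, ko, meta) in hosts.items():
            otu_sel = find_markers(otu, meta,
                                   min_occurrence=config.min_occurrence,
                                   profile=config.network_profile)
            ko_sel = find_markers(ko, meta,
                                  min_occurrence=config.min_occurrence,
                                  profile=config.network_profile)
            hm = meta.index[meta["group"].isin(["H", "M"])]
            graph = build_network(
                otu.subset_samples([s for s in otu.sample_ids if s in set(hm)])
                   .subset_features(otu_sel.index),
                ko.subset_samples([s for s in ko.sample_ids if s in set(hm)])
                  .subset_features(ko_sel.index),
                rho_threshold=config.rho_threshold,
                q_threshold=config.network_q_threshold,
                taxonomy=bundle.taxonomy, pathway_map=bundle.pathway_map)
            networks[host] = graph
            export_network(graph, out / f"network_{host}.tsv", "edge_tsv")
            export_network(graph, out / f"network_{host}.graphml", "graphml")
        report["stages"][stage] = {
            "status": "ok",
            **{f"n_edges_{host}": graph.number_of_edges()
               for host, graph in networks.items()},
        }
    except Exception as exc:
        _fail(report, out, stage, exc)

    # ---- cross-host ------------------------------------------------------
    stage = "crosshost"
    try:
        cross: dict = {}
        for kind in ("otu", "ko"):
            rep = amplification_report(dms["donor", kind], bundle.donor_metadata,
                                       dms["recipient", kind],
                                       bundle.recipient_metadata,
                                       feature_kind=kind)
            cross[f"amplification_{kind}"] = {
                "donor_mean_between": rep.donor_mean_between,
                "recipient_mean_between": rep.recipient_mean_between,
                "fold": rep.fold}
        for rank in ("otu", "genus", "family"):
            overlap = shared_features(bundle.donor_otu, bundle.donor_metadata,
                                      bundle.recipient_otu,
                                      bundle.recipient_metadata,
                                      taxonomy=bundle.taxonomy, rank=rank)
            cross[f"shared_{rank}"] = {g: round(f, 6)
                                       for g, f in overlap.shared_fraction.items()}
        concordant = concordant_markers(marker_frames["donor", "otu"],
                                        marker_frames["recipient", "otu"],
                                        taxonomy=bundle.taxonomy, rank="genus")
        cross["concordant_otu_genera"] = concordant["taxon"].tolist()
        concordant_ko = concordant_markers(marker_frames["donor", "ko"],
                                           marker_frames["recipient", "ko"],
                                           rank="otu")
        cross["n_concordant_kos"] = int(len(concordant_ko))
        with open(out / "crosshost.json", "w") as handle:
            json.dump(cross, handle, indent=1, sort_keys=True)
        report["stages"][stage] = {"status": "ok", **cross}
    except Exception as exc:
        _fail(report, out, stage, exc)

    _write_report(report, out)
    return report


def _fail(report: dict, out: Path, stage: str, exc: Exception):
    report["stages"][stage] = {"status": "failed", "error": str(exc)}
    _write_report(report, out)
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True, default=str)
    lines = [f"crossfmt {report['version']} run report", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}] status={info.get('status')}")
        for key, value in sorted(info.items()):
            if key == "status":
                continue
            lines.append(f"  {key}: {value}")
    with open(out / "report.txt", "w") as handle:
        handle.write("\n".join(lines) + "\n")
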