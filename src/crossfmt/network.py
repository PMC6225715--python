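"""Taxon-function co-occurrence networks.

Differential OTUs and KOs are linked by Spearman correlation of their
abundances across shared samples; an edge is kept when ``|rho|`` exceeds
the threshold (the study uses 0.8) and the BH-adjusted p over all tested
pairs is below ``q_threshold``.  Edge sign records the correlation type
(positive/negative).  Networks are :class:`networkx.Graph` objects with
node attributes ``kind`` (otu/ko) and ``annotation`` (genus for OTUs,
pathway list for KOs) and edge attributes ``rho``, ``p``, ``q``, ``sign``.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .markers import bh_adjust
from .tables import FeatureTable, PathwayMap, TaxonomyMap


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and p (t-approximation); constant input gives (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def build_network(otu_table: FeatureTable, ko_table: FeatureTable,
                  rho_threshold: float = 0.8, q_threshold: float = 0.01,
                  include_same_kind: bool = False,
                  taxonomy: TaxonomyMap | None = None,
                  pathway_map: PathwayMap | None = None) -> nx.Graph:
    """Correlation network over the features of two (marker) tables.

    Tables are typically pre-subset to differential features.  All OTU-KO
    pairs are tested (plus OTU-OTU and KO-KO pairs when
    ``include_same_kind``); edges satisfy ``|rho| > rho_threshold`` and BH
    ``q < q_threshold`` over every tested pair.
    """
    shared = [s for s in otu_table.sample_ids if s in set(ko_table.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    otu_frame = otu_table.data.loc[shared]
    ko_frame = ko_table.data.loc[shared]

    pairs = [(("otu", o), ("ko", k))
             for o in otu_frame.columns for k in ko_frame.columns]
    if include_same_kind:
        pairs += [(("otu", a), ("otu", b))
                  for a, b in combinations(otu_frame.columns, 2)]
        pairs += [(("ko", a), ("ko", b))
                  for a, b in combinations(ko_frame.columns, 2)]

    frames = {"otu": otu_frame, "ko": ko_frame}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for (kind_a, fa), (kind_b, fb) in pairs:
            rho, p = spearman(frames[kind_a][fa], frames[kind_b][fb])
            if np.isnan(rho):
                continue
            rows.append((kind_a, fa, kind_b, fb, rho, p))

    graph = nx.Graph()
    _add_nodes(graph, otu_table, "otu", taxonomy, pathway_map)
    _add_nodes(graph, ko_table, "ko", taxonomy, pathway_map)
    if not rows:
        return graph
    table = pd.DataFrame(rows, columns=["kind_a", "a", "kind_b", "b", "rho", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    keep = (table["rho"].abs() > rho_threshold) & (table["q"] < q_threshold)
    for row in table[keep].itertuples():
        graph.add_edge(row.a, row.b, rho=float(row.rho), p=float(row.p),
                       q=float(row.q),
                       sign="positive" if row.rho > 0 else "negative")
    return graph


def _add_nodes(graph: nx.Graph, table: FeatureTable, kind: str,
               taxonomy: TaxonomyMap | None, pathway_map: PathwayMap | None) -> None:
    for fid in table.feature_ids:
        if kind == "otu" and taxonomy is not None:
            annotation = taxonomy.taxon_at(fid, "genus")
        elif kind == "ko" and pathway_map is not None:
            annotation = ",".join(sorted(pathway_map.pathways_for(fid)))
        else:
            annotation = ""
        graph.add_node(fid, kind=kind, annotation=annotation)


def connected_components(graph: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(graph)]


def export_network(graph: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Write a network as GraphML or an edge-list TSV (with a node table sidecar)."""
    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "edge_tsv":
        with open(path, "w") as handle:
            handle.write("node_a\tnode_b\trho\tp\tq\tsign\n")
            for a, b, attrs in sorted(graph.edges(data=True)):
                handle.write(f"{a}\t{b}\t{attrs['rho']:.10g}\t{attrs['p']:.10g}"
                             f"\t{attrs['q']:.10g}\t{attrs['sign']}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(str(path))
    if format == "edge_tsv":
        graph = nx.Graph()
        frame = pd.read_csv(path, sep="\t")
        for row in frame.itertuples():
            graph.add_edge(str(row.node_a), str(row.node_b), rho=float(row.rho),
                           p=float(row.p), q=float(row.q), sign=str(row.sign))
        return graph
    raise ValueError(f"unknown network format {format!r}")
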