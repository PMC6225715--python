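"""Readers and writers for the pipeline's on-disk formats.

Formats: abundance TSV (features in rows, samples in columns, tab separated,
header row — the orientation of the study's supplementary tables), BIOM 1.0
JSON, newick trees, two-column KO->pathway TSV, three-column sample metadata
TSV and four-column taxonomy TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .tables import FeatureTable, PathwayMap, TaxonomyMap, validate_metadata


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv", kind: str = "otu",
                       normalization: str = "counts") -> FeatureTable:
    """Read an abundance table from ``tsv`` or ``biom`` (JSON dialect)."""
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        # on disk: features x samples -> in memory: samples x features
        data = frame.T
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
    elif format == "biom":
        data = _read_biom_json(path)
    else:
        raise ValueError(f"unknown feature-table format {format!r}")
    if data.index.has_duplicates or data.columns.has_duplicates:
        raise ValueError(f"duplicate ids in {path}")
    if data.size and float(data.to_numpy(dtype=float).min()) < 0:
        raise ValueError(f"negative abundance values in {path}")
    return FeatureTable(data=data, kind=kind, normalization=normalization)


def write_feature_table(table: FeatureTable, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.data.T
        out.index.name = f"#{table.kind.upper()} ID"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown feature-table format {format!r}")


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as handle:
        doc = json.load(handle)
    n_rows, n_cols = doc["shape"]
    row_ids = [r["id"] for r in doc["rows"]]
    col_ids = [c["id"] for c in doc["columns"]]
    if len(row_ids) != n_rows or len(col_ids) != n_cols:
        raise ValueError(f"BIOM shape does not match row/column lists in {path}")
    matrix = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in doc["data"]:
            matrix[int(i), int(j)] = v
    else:
        matrix[:] = np.asarray(doc["data"], dtype=float)
    # BIOM rows are observations (features), columns are samples
    return pd.DataFrame(matrix.T, index=col_ids, columns=row_ids)


def _write_biom_json(table: FeatureTable, path: Path) -> None:
    matrix = table.values().T  # features x samples
    rows, cols = np.nonzero(matrix)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table" if table.kind == "otu" else "Function table",
        "generated_by": "crossfmt",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [matrix.shape[0], matrix.shape[1]],
        "rows": [{"id": fid, "metadata": None} for fid in table.feature_ids],
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
        "data": [[int(i), int(j), float(matrix[i, j])] for i, j in zip(rows, cols)],
    }
    with open(path, "w") as handle:
        json.dump(doc, handle)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def validate_tree_coverage(tree: skbio.TreeNode, feature_ids) -> None:
    """Every OTU id used in phylogenetic distances must be a tree leaf."""
    leaves = {tip.name for tip in tree.tips()}
    missing = sorted(set(feature_ids) - leaves)
    if missing:
        raise ValueError(f"OTU ids missing from tree leaves: {missing}")


# ---------------------------------------------------------------------------
# metadata, pathway map, taxonomy
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, group, host)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "host"}
    if not required <= set(frame.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    frame = frame.set_index("sample_id")
    return validate_metadata(frame)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_pathway_map(path, names_path=None) -> PathwayMap:
    """Read a two-column KO<TAB>pathway TSV (one membership per row)."""
    ko_to_pathways: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            ko, pathway = parts[0], parts[1]
            ko_to_pathways.setdefault(ko, set()).add(pathway)
    names: dict[str, str] = {}
    if names_path is not None:
        with open(names_path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pw, name = line.split("\t")[:2]
                names[pw] = name
    return PathwayMap(ko_to_pathways=ko_to_pathways, pathway_names=names)


def write_pathway_map(pathway_map: PathwayMap, path) -> None:
    with open(path, "w") as handle:
        for ko in sorted(pathway_map.ko_to_pathways):
            for pw in sorted(pathway_map.ko_to_pathways[ko]):
                handle.write(f"{ko}\t{pw}\n")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV (otu_id, phylum, family, genus)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).set_index("otu_id")
    return TaxonomyMap(lineages=frame)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    taxonomy.lineages.rename_axis("otu_id").reset_index().to_csv(
        path, sep="\t", index=False
    )
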