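"""Core data containers: abundance tables, sample metadata, pathway and taxonomy maps.

A :class:`FeatureTable` holds a samples x features nonnegative abundance matrix
(OTU or KO role) on top of a :class:`pandas.DataFrame`.  Sample metadata is a
DataFrame indexed by sample id with ``group`` (H = healthy, M = mastitis,
P = probiotic-treated) and ``host`` (cow donor or mouse recipient) columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_KINDS = ("otu", "ko")
VALID_NORMALIZATIONS = ("counts", "relative")
VALID_GROUPS = ("H", "M", "P")
VALID_HOSTS = ("cow", "mouse")

#: token for a missing taxonomy rank; never matches another feature's rank,
#: not even another "unclassified" one
UNCLASSIFIED = "unclassified"

_REL_TOL = 1e-9


@dataclass
class FeatureTable:
    """Samples x features nonnegative abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and feature ids as columns.
    kind:
        ``"otu"`` for organismal tables, ``"ko"`` for functional (KEGG
        Orthology) tables.
    normalization:
        ``"counts"`` (raw, typically integer) or ``"relative"`` (each sample
        row sums to 1).
    """

    data: pd.DataFrame
    kind: str = "otu"
    normalization: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.normalization not in VALID_NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {VALID_NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("abundance values must be nonnegative")
        if self.normalization == "relative" and values.size:
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _REL_TOL)
            if bad.size:
                raise ValueError(
                    "relative table rows must sum to 1; offending samples: "
                    f"{self.data.index[bad].tolist()}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return replace(self, data=self.data.loc[list(sample_ids)])

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        # dropping columns voids the relative row-sum guarantee
        norm = self.normalization
        if norm == "relative" and len(feature_ids) < self.data.shape[1]:
            norm = "counts"
        return replace(self, data=self.data.loc[:, feature_ids],
                       normalization=norm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.normalization == other.normalization
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.values(), other.values(), rtol=0, atol=1e-12)
        )


def normalize_relative(table: FeatureTable) -> FeatureTable:
    """Scale each sample row to sum to 1 (relative abundances).

    Idempotent.  Raises ``ValueError`` naming the sample if any row is all
    zeros.
    """
    values = table.values()
    sums = values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize all-zero sample(s): {table.data.index[zero].tolist()}"
        )
    data = pd.DataFrame(
        values / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return FeatureTable(data=data, kind=table.kind, normalization="relative")


def filter_occurrence(table: FeatureTable, min_samples: int) -> FeatureTable:
    """Keep features with nonzero abundance in at least ``min_samples`` samples.

    The study's network analysis keeps features occurring in more than five
    samples, i.e. ``min_samples=6``.  Column order is preserved; an empty
    result is allowed.
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    prevalence = (table.values() > 0).sum(axis=0)
    keep = table.data.columns[prevalence >= min_samples]
    return replace(table, data=table.data.loc[:, keep])


def prevalence(table: FeatureTable) -> pd.Series:
    """Number of samples with nonzero abundance, per feature."""
    return pd.Series((table.values() > 0).sum(axis=0), index=table.data.columns)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(metadata: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Validate a metadata frame (index sample_id; columns group, host).

    If ``table`` is given, every table sample must have exactly one record.
    """
    for col in ("group", "host"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if metadata.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    bad_group = set(metadata["group"]) - set(VALID_GROUPS)
    if bad_group:
        raise ValueError(f"invalid group labels: {sorted(bad_group)}")
    bad_host = set(metadata["host"]) - set(VALID_HOSTS)
    if bad_host:
        raise ValueError(f"invalid host labels: {sorted(bad_host)}")
    if table is not None:
        missing = set(table.sample_ids) - set(metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
    return metadata


# ---------------------------------------------------------------------------
# pathway map
# ---------------------------------------------------------------------------

@dataclass
class PathwayMap:
    """Many-to-many KO -> pathway membership plus optional display names."""

    ko_to_pathways: dict[str, set[str]] = field(default_factory=dict)
    pathway_names: dict[str, str] = field(default_factory=dict)

    def pathways_for(self, ko: str) -> set[str]:
        return self.ko_to_pathways.get(ko, set())

    def pathway_to_kos(self) -> dict[str, set[str]]:
        inverse: dict[str, set[str]] = {}
        for ko, pathways in self.ko_to_pathways.items():
            for pw in pathways:
                inverse.setdefault(pw, set()).add(ko)
        return inverse

    def name(self, pathway: str) -> str:
        return self.pathway_names.get(pathway, pathway)

    def __len__(self) -> int:
        return len(self.pathway_to_kos())


# ---------------------------------------------------------------------------
# taxonomy map
# ---------------------------------------------------------------------------

RANKS = ("phylum", "family", "genus")


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage (phylum, family, genus).

    Missing ranks are stored as the explicit :data:`UNCLASSIFIED` token;
    such entries never match each other when taxa are compared across
    hosts.
    """

    lineages: pd.DataFrame  # index otu id, columns phylum/family/genus

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise ValueError(f"taxonomy is missing rank column(s): {missing}")
        self.lineages = self.lineages.fillna(UNCLASSIFIED)
        # consistency: one genus never spans two families (unclassified exempt)
        known = self.lineages[self.lineages["genus"] != UNCLASSIFIED]
        fam_per_genus = known.groupby("genus")["family"].nunique()
        bad = fam_per_genus[fam_per_genus > 1]
        if len(bad):
            raise ValueError(
                f"contradictory taxonomy: genus in multiple families: {bad.index.tolist()}"
            )

    def taxon_at(self, otu: str, rank: str) -> str:
        if rank == "otu":
            return otu
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        if otu not in self.lineages.index:
            return UNCLASSIFIED
        return str(self.lineages.at[otu, rank])

    def taxa_at(self, otus, rank: str) -> pd.Series:
        return pd.Series({o: self.taxon_at(o, rank) for o in otus})
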