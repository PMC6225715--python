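"""Donor-vs-recipient comparison across the transplantation.

Three questions about a cow (donor) to mouse (recipient) FMT study:

* how much of the recipient community traces back to the donor, per group
  pairing (healthy->healthy, mastitis->mastitis), at OTU / genus / family
  resolution;
* which markers keep their direction of change across hosts;
* how strongly the health-disease divergence is amplified by
  transplantation — the ratio of mean between-group community distance in
  the recipient versus the donor ("amplification effect").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .tables import UNCLASSIFIED, FeatureTable, TaxonomyMap, normalize_relative


def mean_between_group_distance(dm: DistanceMatrix, metadata: pd.DataFrame,
                                group_a: str, group_b: str) -> float:
    """Mean of d(i, j) over all pairs with i in group_a and j in group_b."""
    if group_a == group_b:
        raise ValueError("between-group distance needs two distinct groups")
    ids = list(dm.ids)
    groups = metadata.loc[ids, "group"]
    idx_a = [k for k, s in enumerate(ids) if groups[s] == group_a]
    idx_b = [k for k, s in enumerate(ids) if groups[s] == group_b]
    if not idx_a or not idx_b:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    block = np.asarray(dm.data)[np.ix_(idx_a, idx_b)]
    return float(block.mean())


def amplification_factor(donor_mean: float, recipient_mean: float) -> float:
    """Ratio of recipient to donor mean between-group distance."""
    if donor_mean <= 0:
        raise ValueError("donor mean distance must be positive")
    return float(recipient_mean) / float(donor_mean)


def format_fold(fold: float) -> str:
    """Integer presentation used in prose, e.g. 22.88 -> "23-fold"."""
    return f"{int(np.floor(fold + 0.5))}-fold"


@dataclass
class AmplificationReport:
    feature_kind: str
    donor_mean_between: float
    recipient_mean_between: float
    fold: float


def amplification_report(donor_dm: DistanceMatrix, donor_meta: pd.DataFrame,
                         recipient_dm: DistanceMatrix, recipient_meta: pd.DataFrame,
                         group_a: str = "H", group_b: str = "M",
                         feature_kind: str = "otu") -> AmplificationReport:
    donor_mean = mean_between_group_distance(donor_dm, donor_meta, group_a, group_b)
    recipient_mean = mean_between_group_distance(recipient_dm, recipient_meta,
                                                 group_a, group_b)
    return AmplificationReport(feature_kind, donor_mean, recipient_mean,
                               amplification_factor(donor_mean, recipient_mean))


# ---------------------------------------------------------------------------
# shared features across hosts
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    rank: str
    weighted: bool
    #: group label -> fraction of recipient abundance (or feature count)
    #: attributable to taxa present in the matching donor group
    shared_fraction: dict[str, float] = field(default_factory=dict)
    shared_taxa: dict[str, list[str]] = field(default_factory=dict)


def shared_features(donor_table: FeatureTable, donor_meta: pd.DataFrame,
                    recipient_table: FeatureTable, recipient_meta: pd.DataFrame,
                    taxonomy: TaxonomyMap | None = None, rank: str = "otu",
                    groups: tuple[str, ...] = ("H", "M"),
                    weighted: bool = True) -> OverlapReport:
    """Fraction of each recipient group's community traceable to its donor group.

    A recipient feature is "shared" when its rank-level taxon occurs
    (nonzero in at least one sample) in the paired donor group; at
    ``rank="otu"`` sharing means exact id match.  Features whose taxon is
    :data:`UNCLASSIFIED` never match.  ``weighted=True`` weights by mean
    recipient relative abundance; otherwise by feature count.
    """
    if rank != "otu" and taxonomy is None:
        raise ValueError(f"rank={rank!r} requires a taxonomy map")
    donor_rel = normalize_relative(donor_table)
    recip_rel = normalize_relative(recipient_table)
    report = OverlapReport(rank=rank, weighted=weighted)
    for group in groups:
        donor_samples = donor_meta.index[donor_meta["group"] == group]
        recip_samples = recipient_meta.index[recipient_meta["group"] == group]
        donor_sub = donor_rel.data.loc[[s for s in donor_rel.sample_ids
                                        if s in set(donor_samples)]]
        recip_sub = recip_rel.data.loc[[s for s in recip_rel.sample_ids
                                        if s in set(recip_samples)]]
        if not len(donor_sub) or not len(recip_sub):
            raise ValueError(f"group {group!r} empty in donor or recipient")
        donor_present = donor_sub.columns[(donor_sub > 0).any(axis=0)]
        donor_taxa = {_taxon(f, taxonomy, rank) for f in donor_present}
        donor_taxa.discard(UNCLASSIFIED)

        recip_present = recip_sub.columns[(recip_sub > 0).any(axis=0)]
        recip_taxon = {f: _taxon(f, taxonomy, rank) for f in recip_present}
        shared = [f for f, t in recip_taxon.items()
                  if t != UNCLASSIFIED and t in donor_taxa]
        if weighted:
            mean_ab = recip_sub.mean(axis=0)
            total = float(mean_ab[recip_present].sum())
            fraction = float(mean_ab[shared].sum()) / total if total > 0 else 0.0
        else:
            fraction = len(shared) / len(recip_present) if len(recip_present) else 0.0
        report.shared_fraction[group] = fraction
        report.shared_taxa[group] = sorted({recip_taxon[f] for f in shared})
    return report


def _taxon(feature_id: str, taxonomy: TaxonomyMap | None, rank: str) -> str:
    if rank == "otu":
        return feature_id
    assert taxonomy is not None
    return taxonomy.taxon_at(feature_id, rank)


# ---------------------------------------------------------------------------
# direction-concordant markers
# ---------------------------------------------------------------------------

def concordant_markers(donor_markers: pd.DataFrame, recipient_markers: pd.DataFrame,
                       taxonomy: TaxonomyMap | None = None,
                       rank: str = "otu") -> pd.DataFrame:
    """Features (or rank-level taxa) significant in both hosts with equal direction.

    Marker frames come from :func:`crossfmt.markers.find_markers` (need the
    ``sign`` column).  For KO markers use ``rank="otu"`` semantics (exact id
    match) — pass ``rank="otu"``.  At genus/family rank, a taxon is
    concordant when both hosts have a marker mapping to it and every such
    marker agrees in sign; :data:`UNCLASSIFIED` taxa never match.
    """
    donor_sign = _rank_signs(donor_markers, taxonomy, rank)
    recip_sign = _rank_signs(recipient_markers, taxonomy, rank)
    rows = []
    for taxon in sorted(set(donor_sign) & set(recip_sign)):
        if donor_sign[taxon] == recip_sign[taxon] and donor_sign[taxon] != 0:
            rows.append({"taxon": taxon, "sign": donor_sign[taxon],
                         "direction": "up_in_M" if donor_sign[taxon] > 0
                         else "down_in_M"})
    return pd.DataFrame(rows, columns=["taxon", "sign", "direction"])


def _rank_signs(markers: pd.DataFrame, taxonomy: TaxonomyMap | None,
                rank: str) -> dict[str, int]:
    signs: dict[str, int] = {}
    for fid, row in markers.iterrows():
        taxon = _taxon(str(fid), taxonomy, rank)
        if taxon == UNCLASSIFIED:
            continue
        sign = int(row["sign"])
        if taxon in signs and signs[taxon] != sign:
            signs[taxon] = 0  # conflicting directions within one taxon
        else:
            signs.setdefault(taxon, sign)
    return signs
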