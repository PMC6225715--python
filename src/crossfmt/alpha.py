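"""Per-sample alpha diversity: observed features, Shannon, Simpson, Chao1.

Index conventions (the study names the indices without formulas): Shannon
entropy in nats by default (base configurable), Simpson in the Gini-Simpson
form ``1 - sum(p_i^2)``, and bias-corrected Chao1
``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` with ``F1``/``F2`` the singleton and
doubleton counts.  Computed on raw counts, without rarefaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.diversity import alpha as skbio_alpha

from .tables import FeatureTable


def shannon(abundances, base: float = np.e) -> float:
    """Shannon entropy ``-sum p_i log_base p_i`` over nonzero proportions."""
    counts = np.asarray(abundances, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("Shannon index requires a positive total abundance")
    if np.any(counts < 0):
        raise ValueError("abundances must be nonnegative")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def simpson(abundances) -> float:
    """Gini-Simpson index ``1 - sum(p_i^2)``; 0 for a single taxon."""
    counts = np.asarray(abundances, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("Simpson index requires a positive total abundance")
    p = counts / counts.sum()
    return float(1.0 - (p ** 2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate from integer counts."""
    arr = np.asarray(counts)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer counts")
    return float(skbio_alpha.chao1(arr.astype(int), bias_corrected=True))


def observed(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def alpha_diversity(table: FeatureTable, base: float = np.e) -> pd.DataFrame:
    """All four indices per sample; Chao1 only for count tables."""
    values = table.values()
    records = {}
    is_counts = table.normalization == "counts" and np.allclose(
        values, np.round(values)
    )
    for sid, row in zip(table.sample_ids, values):
        records[sid] = {
            "observed": observed(row),
            "shannon": shannon(row, base=base),
            "simpson": simpson(row),
            "chao1": chao1(row) if is_counts else np.nan,
        }
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame.index.name = "sample_id"
    return frame
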