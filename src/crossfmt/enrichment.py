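"""Reporter-score pathway enrichment.

KO-level significance is aggregated to pathways through inverse-normal
scores: each tested KO contributes ``z = Phi^-1(1 - p)``; a pathway with
``k`` tested member KOs scores ``Z_raw = sum(z) / sqrt(k)``; the raw score
is background-normalized against random size-``k`` KO sets drawn from the
pool of all tested KOs, ``Z_adj = (Z_raw - mean) / sd``.  A pathway is
called significant when ``Z_adj`` exceeds the detection threshold 1.6
(the 90% two-sided normal quantile, 1.645, at the study's one-decimal
precision).

Direction: member KOs are called up- or down-regulated by one-sided
rank-sum tests at ``alpha``; a pathway is "up" only when the up count is at
least 10% larger than the down count (``n_up >= 1.1 * n_down``), "down"
symmetrically, otherwise "mixed".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PathwayMap

_P_CLAMP = 1e-15


def ko_z(p: float) -> float:
    """Inverse-normal score ``Phi^-1(1 - p)``; large for small p."""
    p = float(p)
    if p < 0.0 or p > 1.0:
        warnings.warn(f"p={p} outside [0, 1]; clamping", stacklevel=2)
    p = float(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))
    return float(stats.norm.isf(p))


def pathway_z(z_list) -> float:
    """Aggregate member scores: ``Z = sum(z_i) / sqrt(k)``."""
    z = np.asarray(z_list, dtype=float)
    if z.size == 0:
        raise ValueError("pathway has no tested KOs")
    return float(z.sum() / np.sqrt(z.size))


def background_correct(z_raw: float, k: int, z_pool, n_draws: int = 1000,
                       seed: int | None = None) -> float:
    """Normalize a raw pathway score against random size-``k`` KO sets.

    Draws ``n_draws`` subsets (without replacement within a draw) from
    ``z_pool``, scores each with :func:`pathway_z`, and returns
    ``(z_raw - mean) / sd``.
    """
    pool = np.asarray(z_pool, dtype=float)
    if pool.size < k:
        raise ValueError(f"background pool ({pool.size}) smaller than pathway size {k}")
    rng = np.random.default_rng(seed)
    # k smallest of random keys per row = a uniform size-k subset
    keys = rng.random((n_draws, pool.size))
    subset_idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_scores = pool[subset_idx].sum(axis=1) / np.sqrt(k)
    sd = null_scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate background pool (zero variance)")
    return float((z_raw - null_scores.mean()) / sd)


def classify_direction(n_up: int, n_down: int) -> str:
    """Up iff ``n_up >= 1.1 * n_down`` (and nonzero); down symmetrically."""
    if n_up > 0 and n_up >= 1.1 * n_down:
        return "up"
    if n_down > 0 and n_down >= 1.1 * n_up:
        return "down"
    return "mixed"


def enrich(ko_stats: pd.DataFrame, pathway_map: PathwayMap,
           z_threshold: float = 1.6, wilcoxon_alpha: float = 0.05,
           n_draws: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Score every pathway with at least one tested KO.

    ``ko_stats`` is the full per-KO statistics frame from
    :func:`crossfmt.markers.differential_stats` (columns ``p_two``, ``p_up``,
    ``p_down``).  Returns a frame indexed by pathway id with columns ``k``,
    ``z_raw``, ``z_adj``, ``n_up``, ``n_down``, ``direction``,
    ``fraction_label`` and ``significant`` (``z_adj > z_threshold``).
    """
    if not len(ko_stats):
        return pd.DataFrame(columns=["name", "k", "z_raw", "z_adj", "n_up",
                                     "n_down", "direction", "fraction_label",
                                     "significant"])
    z_scores = ko_stats["p_two"].map(ko_z)
    up = ko_stats["p_up"] < wilcoxon_alpha
    down = ko_stats["p_down"] < wilcoxon_alpha
    pool = z_scores.to_numpy()

    rng = np.random.default_rng(seed)
    records = []
    for pathway, members in sorted(pathway_map.pathway_to_kos().items()):
        tested = [ko for ko in sorted(members) if ko in ko_stats.index]
        k = len(tested)
        if k == 0:
            continue
        z_raw = pathway_z(z_scores[tested].to_numpy())
        z_adj = background_correct(z_raw, k, pool, n_draws=n_draws,
                                   seed=int(rng.integers(2 ** 31)))
        n_up = int(up[tested].sum())
        n_down = int(down[tested].sum())
        direction = classify_direction(n_up, n_down)
        n_changed = {"up": n_up, "down": n_down}.get(direction, n_up + n_down)
        records.append({
            "pathway_id": pathway,
            "name": pathway_map.name(pathway),
            "k": k,
            "z_raw": z_raw,
            "z_adj": z_adj,
            "n_up": n_up,
            "n_down": n_down,
            "direction": direction,
            "fraction_label": f"{n_changed}/{k}",
            "significant": bool(z_adj > z_threshold),
        })
    return pd.DataFrame.from_records(records).set_index("pathway_id")


def write_pathway_scores(scores: pd.DataFrame, path) -> None:
    scores.rename_axis("pathway_id").to_csv(path, sep="\t")
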