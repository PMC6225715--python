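"""Differential-abundance marker discovery.

Per-feature two-group Wilcoxon rank-sum (Mann-Whitney) tests with
Benjamini-Hochberg correction, direction and effect annotation.  The exact
null distribution is enumerated for small tie-free inputs
(``n_x + n_y <= 12``); otherwise the tie-corrected normal approximation with
continuity correction is used.

The study applies different thresholds to different feature classes; these
ship as named profiles:

* ``paper-otu``: BH-adjusted q < 0.01 (organismal markers),
* ``paper-ko``: unadjusted p < 0.05 (functional markers),
* ``paper-network``: one-tail test, q < 0.01 (network feature selection),
* ``default``: q < 0.1 (the global threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, filter_occurrence, normalize_relative, prevalence

LOG2_PSEUDOCOUNT = 1e-6

_ALT_MAP = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class MarkerProfile:
    """Threshold bundle for one analysis flavour."""

    threshold: float
    use_adjusted: bool
    mode: str = "two_sided"  # or "one_tail"


PROFILES: dict[str, MarkerProfile] = {
    "default": MarkerProfile(threshold=0.1, use_adjusted=True),
    "paper-otu": MarkerProfile(threshold=0.01, use_adjusted=True),
    "paper-ko": MarkerProfile(threshold=0.05, use_adjusted=False),
    "paper-network": MarkerProfile(threshold=0.01, use_adjusted=True, mode="one_tail"),
}


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum p-value comparing samples ``x`` and ``y``.

    ``alternative="greater"`` tests whether ``x`` is stochastically greater
    than ``y``.  Exact enumeration when ``len(x)+len(y) <= 12`` with no ties
    across the pooled data; otherwise normal approximation with mid-ranks,
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in _ALT_MAP:
        raise ValueError(f"alternative must be one of {sorted(_ALT_MAP)}")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=_ALT_MAP[alternative],
                             method=method, use_continuity=True)
    return float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_stats(table: FeatureTable, metadata: pd.DataFrame,
                  group_a: str = "H", group_b: str = "M",
                  min_occurrence: int = 6, relative: bool = True,
                  mode: str = "two_sided") -> pd.DataFrame:
    """Per-feature statistics for ``group_b`` vs ``group_a``; all tested features.

    Returns a DataFrame indexed by feature id with columns ``p`` (per the
    configured mode), ``p_two``, ``p_up``, ``p_down`` (one-sided: feature
    higher/lower in ``group_b``), ``q`` (BH over tested features), ``effect``
    (difference of group mean relative abundances, ``group_b - group_a``),
    ``log2_ratio`` (with pseudocount), ``direction`` and ``sign``
    (+1 = up in ``group_b``), and ``prevalence``.
    """
    meta = metadata.loc[[s for s in table.sample_ids if s in metadata.index]]
    samples_a = meta.index[meta["group"] == group_a].tolist()
    samples_b = meta.index[meta["group"] == group_b].tolist()
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(samples_a)} in {group_a!r} "
            f"and {len(samples_b)} in {group_b!r}"
        )
    if mode not in ("two_sided", "one_tail"):
        raise ValueError("mode must be 'two_sided' or 'one_tail'")

    selected = table.subset_samples(samples_a + samples_b)
    selected = filter_occurrence(selected, min_occurrence)
    prev = prevalence(selected)
    work = normalize_relative(selected) if relative else selected
    frame = work.data
    a_idx = frame.index.isin(samples_a)
    b_idx = frame.index.isin(samples_b)

    records = []
    for fid in frame.columns:
        xa = frame.loc[a_idx, fid].to_numpy()
        xb = frame.loc[b_idx, fid].to_numpy()
        p_two = wilcoxon_rank_sum(xb, xa, "two_sided")
        p_up = wilcoxon_rank_sum(xb, xa, "greater")
        p_down = wilcoxon_rank_sum(xb, xa, "less")
        mean_a, mean_b = xa.mean(), xb.mean()
        sign = 1 if mean_b >= mean_a else -1
        records.append({
            "feature_id": fid,
            "p_two": p_two,
            "p_up": p_up,
            "p_down": p_down,
            "p": p_two if mode == "two_sided" else min(p_up, p_down),
            "effect": mean_b - mean_a,
            "log2_ratio": float(np.log2((mean_b + LOG2_PSEUDOCOUNT)
                                        / (mean_a + LOG2_PSEUDOCOUNT))),
            "sign": sign,
            "direction": f"up_in_{group_b}" if sign > 0 else f"down_in_{group_b}",
            "prevalence": int(prev[fid]),
        })
    result = pd.DataFrame.from_records(records).set_index("feature_id") if records \
        else pd.DataFrame(columns=["p_two", "p_up", "p_down", "p", "effect",
                                   "log2_ratio", "sign", "direction",
                                   "prevalence"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
    else:
        result["q"] = []
    return result


def find_markers(table: FeatureTable, metadata: pd.DataFrame,
                 group_a: str = "H", group_b: str = "M",
                 min_occurrence: int = 6, relative: bool = True,
                 profile: str | MarkerProfile = "default") -> pd.DataFrame:
    """Significant differential features under a threshold profile.

    Selection is ``q < threshold`` when the profile uses BH adjustment and
    ``p < threshold`` otherwise, over the :func:`differential_stats` output.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    stats_frame = differential_stats(table, metadata, group_a=group_a, group_b=group_b,
                                min_occurrence=min_occurrence, relative=relative,
                                mode=profile.mode)
    if not len(stats_frame):
        return stats_frame
    column = "q" if profile.use_adjusted else "p"
    return stats_frame[stats_frame[column] < profile.threshold]


def write_markers(markers: pd.DataFrame, path) -> None:
    cols = ["p", "q", "direction", "effect", "log2_ratio", "prevalence"]
    markers[cols].rename_axis("feature_id").to_csv(path, sep="\t")
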