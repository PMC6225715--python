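"""Ordination and permutation tests on distance matrices.

PCoA uses Gower double-centering of ``-d^2 / 2`` followed by an
eigendecomposition; negative eigenvalues (possible for semi-metric inputs)
are reported but excluded from coordinates and from the
proportion-explained denominator.  PERMANOVA computes the pseudo-F

    F = (SS_between / (a - 1)) / (SS_within / (N - a))

from squared distances (``SS_total = sum_{i<j} d_ij^2 / N``; within-group
sums divided by group size), with the p-value from label permutations:
``p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1)``, or from exhaustive
enumeration of all distinct relabelings when requested.  Procrustes
concordance of two ordinations is scored by the scaled residual ``M^2``
with a row-permutation Monte-Carlo p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from skbio.stats.distance import DistanceMatrix

from .tables import FeatureTable

_EIG_TOL = 1e-10


@dataclass
class Ordination:
    """Sample coordinates on orthogonal axes ordered by decreasing eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues
    method: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class PermanovaResult:
    F: float
    p: float
    n_permutations: int
    seed: int | None = None


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ (d ** 2) @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > _EIG_TOL * scale
    if positive.any():
        coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
        proportions = eigvals[positive] / eigvals[positive].sum()
    else:  # degenerate: all samples coincide
        coords = np.zeros((n, 1))
        proportions = np.zeros(1)
    return Ordination(list(dm.ids), coords, eigvals, proportions, "pcoa")


def pca(table: FeatureTable) -> Ordination:
    """Principal component analysis of a feature table (centered, unscaled)."""
    x = table.values()
    centered = x - x.mean(axis=0)
    n = x.shape[0]
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s ** 2 / max(n - 1, 1)
    keep = eigvals > _EIG_TOL * max(eigvals[0], 1.0) if eigvals.size else np.zeros(0, bool)
    if eigvals.size and keep.any():
        coords = (u * s)[:, keep]
        proportions = eigvals[keep] / eigvals.sum()
    else:
        coords = np.zeros((n, 1))
        proportions = np.zeros(1)
        eigvals = np.zeros(1)
    return Ordination(table.sample_ids, coords, eigvals, proportions, "pca")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(d_squared: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d_squared.shape[0]
    ss_total = d_squared[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 2:
            continue
        block = d_squared[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def _distinct_relabelings(codes: np.ndarray):
    """All distinct arrangements of a label multiset."""
    from sympy.utilities.iterables import multiset_permutations

    for perm in multiset_permutations(codes.tolist()):
        yield np.asarray(perm)


def permanova(dm: DistanceMatrix, grouping, n_permutations: int | str = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` is a mapping/Series of sample id -> group label (or a
    sequence aligned with ``dm.ids``).  ``n_permutations`` may be the string
    ``"exact"`` to enumerate every distinct relabeling (small n only).
    """
    ids = list(dm.ids)
    if hasattr(grouping, "__getitem__") and not isinstance(grouping, (list, tuple, np.ndarray)):
        labels = np.asarray([grouping[i] for i in ids])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != len(ids):
            raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"each group needs >= 2 samples; too small: {small}")
    d_squared = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d_squared, codes, uniq.size)

    if n_permutations == "exact":
        f_all = [_pseudo_f(d_squared, perm, uniq.size)
                 for perm in _distinct_relabelings(codes)]
        f_all = np.asarray(f_all)
        p = float((f_all >= f_obs - 1e-12).sum() / f_all.size)
        return PermanovaResult(float(f_obs), p, int(f_all.size), seed)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        f_perm = _pseudo_f(d_squared, rng.permutation(codes), uniq.size)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (int(n_permutations) + 1)
    return PermanovaResult(float(f_obs), float(p), int(n_permutations), seed)


# ---------------------------------------------------------------------------
# Procrustes Monte Carlo
# ---------------------------------------------------------------------------

def _take_axes(ordination: Ordination, n_axes: int) -> np.ndarray:
    coords = ordination.coordinates
    if coords.shape[1] < n_axes:
        pad = np.zeros((coords.shape[0], n_axes - coords.shape[1]))
        coords = np.hstack([coords, pad])
    return coords[:, :n_axes]


def procrustes_mc(ord_a: Ordination, ord_b: Ordination, n_axes: int = 2,
                  n_permutations: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Procrustes concordance of two ordinations over their first axes.

    Returns ``(m2, p)``: the minimized scaled residual sum of squares after
    optimal translation/rotation/scaling of unit-trace configurations, and a
    Monte-Carlo p-value from permuting sample rows of the second
    configuration (small p = concordant beyond chance).
    """
    if ord_a.sample_ids != ord_b.sample_ids:
        if set(ord_a.sample_ids) != set(ord_b.sample_ids):
            raise ValueError("ordinations must cover the same samples")
        reorder = [ord_b.sample_ids.index(s) for s in ord_a.sample_ids]
        ord_b = Ordination(ord_a.sample_ids, ord_b.coordinates[reorder],
                           ord_b.eigenvalues, ord_b.proportion_explained, ord_b.method)
    n = len(ord_a.sample_ids)
    if n < 3:
        raise ValueError("Procrustes needs at least 3 samples")
    a = _take_axes(ord_a, n_axes)
    b = _take_axes(ord_b, n_axes)
    _, _, m2 = _scipy_procrustes(a, b)
    rng = np.random.default_rng(seed)
    at_least_as_good = 0
    for _ in range(n_permutations):
        _, _, m2_perm = _scipy_procrustes(a, b[rng.permutation(n)])
        if m2_perm <= m2 + 1e-12:
            at_least_as_good += 1
    p = (at_least_as_good + 1) / (n_permutations + 1)
    return float(m2), float(p)


def write_ordination(ordination: Ordination, path) -> None:
    frame = ordination.to_frame()
    with open(path, "w") as handle:
        handle.write(f"# method: {ordination.method}\n")
        handle.write("# eigenvalues: "
                     + "\t".join(f"{v:.10g}" for v in ordination.eigenvalues) + "\n")
        handle.write("# proportion_explained: "
                     + "\t".join(f"{v:.10g}" for v in ordination.proportion_explained) + "\n")
        frame.rename_axis("sample_id").to_csv(handle, sep="\t")
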