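"""Permutation test for differential heterogeneity between two cell
groups, evaluated per region set.

The observed statistic per region set is the difference of
adjusted-but-unscaled scores between the two groups (the run's min-max
transform is deliberately omitted: over two groups it would force 0 and
1).  The null is built by re-splitting the pooled cells into
pseudo-groups of the original sizes; one shared permutation stream
serves all region sets so that results are paired across sets and
reproducible from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import adjust_scores, pairwise_centered_jaccard
from .regions import overlap_mask
from .types import BinaryMatrix, EpichaosWarning, InputError, RegionSet, validate_feature_table

__all__ = ["DifferentialResult", "differential_heterogeneity"]


@dataclass(frozen=True)
class DifferentialResult:
    region_set: str
    delta: float  # heterogeneity(groupA) - heterogeneity(groupB), adjusted unscaled
    p_value: float
    n_features: int
    n_permutations: int


def _subset_stats(C: np.ndarray, counts: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    """Raw score and mean count of a cell subset from precomputed pool stats."""
    k = idx.size
    sub = C[np.ix_(idx, idx)]
    raw = (sub.sum() - np.trace(sub)) / (k * (k - 1))
    return float(raw), float(counts[idx].mean())


def _deltas(
    pools: Sequence[tuple[np.ndarray, np.ndarray]],
    idx_a: np.ndarray,
    idx_b: np.ndarray,
) -> np.ndarray:
    """Per-region-set adjusted-score differences for one split of the pool."""
    raws, mcs = [], []
    for C, counts in pools:
        ra, ma = _subset_stats(C, counts, idx_a)
        rb, mb = _subset_stats(C, counts, idx_b)
        raws.extend([ra, rb])
        mcs.extend([ma, mb])
    adjusted, _ = adjust_scores(raws, mcs)
    # adjusted residuals are on the similarity scale; negate so that a
    # positive delta means group A is the more heterogeneous one, in line
    # with the orientation of the final score
    return adjusted[1::2] - adjusted[0::2]


def differential_heterogeneity(
    m: BinaryMatrix,
    features: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    region_sets: Sequence[RegionSet],
    n_perm: int = 1000,
    seed: int = 0,
    min_features: int = 20,
    two_sided: bool = True,
) -> list[DifferentialResult]:
    """Permutation p-values for score differences between two cell groups.

    For each region set, the observed difference ``delta`` between the
    groups is compared against ``n_perm`` random re-splits of the pooled
    cells into pseudo-groups of sizes |A| and |B|; the p-value uses
    add-one smoothing: ``p = (1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1)``
    (one-sided variant compares signed differences).
    """
    features = validate_feature_table(features, m.n_features)
    group_a = sorted(group_a)
    group_b = sorted(group_b)
    if set(group_a) & set(group_b):
        raise InputError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("each group needs at least 2 cells")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-values; >= 100 recommended",
            EpichaosWarning,
        )

    # canonical pool order (independent of which group is named A) so the
    # permutation stream, and hence p, is invariant under swapping A and B
    pool_cells = sorted(pool for pool in group_a + group_b)
    pool_pos = {c: i for i, c in enumerate(pool_cells)}
    pool_idx = m.cell_indices(pool_cells)
    n_a, n_b = len(group_a), len(group_b)
    n_pool = n_a + n_b

    pools = []
    kept = []
    for rs in region_sets:
        mask = overlap_mask(features, rs)
        n_feat = int(mask.sum())
        if n_feat < min_features:
            warnings.warn(
                f"region set {rs.name!r} retains {n_feat} < {min_features} features; skipped",
                EpichaosWarning,
            )
            continue
        X = m.subset_rows(mask).dense_columns(pool_idx)
        pools.append((pairwise_centered_jaccard(X), X.sum(axis=0).astype(np.float64)))
        kept.append((rs.name, n_feat))
    if not pools:
        raise InputError("no region set passes the min_features filter")

    ia = np.array([pool_pos[c] for c in group_a], dtype=np.intp)
    ib = np.array([pool_pos[c] for c in group_b], dtype=np.intp)
    obs = _deltas(pools, ia, ib)

    # canonical split sizes (larger part first) keep the permutation
    # stream identical when A and B are swapped, so p is symmetric
    rng = np.random.default_rng(seed)
    k_big = max(n_a, n_b)
    perm_deltas = np.empty((n_perm, len(pools)))
    for t in range(n_perm):
        perm = rng.permutation(n_pool)
        big, small = perm[:k_big], perm[k_big:]
        if n_a >= n_b:
            perm_deltas[t] = _deltas(pools, big, small)
        else:
            perm_deltas[t] = _deltas(pools, small, big)

    results = []
    for j, (name, n_feat) in enumerate(kept):
        if two_sided:
            exceed = np.count_nonzero(np.abs(perm_deltas[:, j]) >= abs(obs[j]))
        else:
            exceed = np.count_nonzero(perm_deltas[:, j] >= obs[j])
        p = (1 + exceed) / (n_perm + 1)
        results.append(DifferentialResult(name, float(obs[j]), float(p), n_feat, n_perm))
    return results
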