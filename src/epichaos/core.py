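"""Per-group heterogeneity scoring.

The score for a group of cells is built in four stages:

1. chance-centered Jaccard similarity for every unordered cell pair,
2. the per-group mean of those pairwise values (the raw score),
3. an ordinary-least-squares adjustment of raw scores against the mean
   per-cell detected-feature count, taken across all observations of the
   run (residuals become the adjusted scores),
4. a min-max transform to [0, 1] followed by inversion, so that 1 marks
   the most heterogeneous group of the run.

Scores are therefore *relative to the run*: the raw and adjusted columns
are always emitted alongside the final score so that absolute
comparisons across runs remain possible.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    BinaryMatrix,
    DegenerateRunWarning,
    EpichaosWarning,
    InputError,
    PairSimilarity,
    Replicate,
    validate_feature_table,
)

__all__ = [
    "binarize",
    "centered_jaccard_pair",
    "pairwise_centered_jaccard",
    "raw_group_score",
    "adjust_scores",
    "finalize_scores",
    "subsample_groups",
    "compute_epichaos",
    "per_chromosome_scores",
]

SCORE_COLUMNS = [
    "group",
    "replicate",
    "n_cells",
    "mean_count",
    "raw",
    "adjusted",
    "epichaos",
    "flags",
]


def binarize(
    counts,
    feature_ids: Sequence[str] | None = None,
    cell_ids: Sequence[str] | None = None,
) -> BinaryMatrix:
    """Threshold a non-negative count matrix at zero: entry = 1 iff count > 0."""
    import scipy.sparse as sp

    if isinstance(counts, BinaryMatrix):
        return counts
    if sp.issparse(counts):
        data = counts.tocsr(copy=True)
        if data.nnz and (not np.all(np.isfinite(data.data)) or np.any(data.data < 0)):
            raise InputError("counts must be finite and non-negative")
        data.data = np.ones_like(data.data, dtype=np.uint8)
        nf, nc = data.shape
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(nf)]
        if cell_ids is None:
            cell_ids = [f"c{j}" for j in range(nc)]
        return BinaryMatrix(sp.csr_matrix(data, dtype=np.uint8), np.asarray(feature_ids, dtype=object), np.asarray(cell_ids, dtype=object))
    arr = np.asarray(counts)
    if not np.all(np.isfinite(arr)):
        raise InputError("counts must be finite")
    if np.any(arr < 0):
        raise InputError("counts must be non-negative")
    return BinaryMatrix.from_dense((arr > 0).astype(np.uint8), feature_ids, cell_ids)


# ---------------------------------------------------------------------------
# pairwise similarity
# ---------------------------------------------------------------------------

def _expected_jaccard(p1: float, p2: float) -> float:
    d = p1 + p2 - p1 * p2
    return (p1 * p2 / d) if d > 0 else 0.0


def centered_jaccard_pair(x, y, cell_i: str = "i", cell_j: str = "j") -> PairSimilarity:
    """Chance-centered Jaccard similarity of two equal-length binary vectors.

    With ``a = |x & y|`` and per-vector 1-counts ``s1, s2`` over length n:
    ``J = a / (s1 + s2 - a)`` and the independence expectation
    ``E = p1*p2 / (p1 + p2 - p1*p2)`` with ``p_i = s_i / n``; the centered
    value is ``J - E``.  A pair of two all-zero vectors yields 0 for all
    three quantities (with a warning): empty cells carry no signal.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n == 0:
        raise InputError("vectors must have length >= 1")
    xb = x.astype(bool)
    yb = y.astype(bool)
    s1 = int(xb.sum())
    s2 = int(yb.sum())
    a = int((xb & yb).sum())
    if s1 + s2 == 0:
        warnings.warn(
            "pair of all-zero cells: similarity defined as 0", EpichaosWarning
        )
        return PairSimilarity(cell_i, cell_j, 0.0, 0.0, 0.0)
    j = a / (s1 + s2 - a)
    e = _expected_jaccard(s1 / n, s2 / n)
    return PairSimilarity(cell_i, cell_j, j, e, j - e)


def pairwise_centered_jaccard(X: np.ndarray) -> np.ndarray:
    """All-pairs centered Jaccard for the columns of a dense binary block.

    Returns a symmetric (k x k) matrix; the diagonal is not meaningful
    and callers must ignore it.
    """
    n = X.shape[0]
    Xf = X.astype(np.float64)
    s = Xf.sum(axis=0)
    A = Xf.T @ Xf
    U = s[:, None] + s[None, :] - A
    J = np.divide(A, U, out=np.zeros_like(A), where=U > 0)
    p = s / n
    P = np.outer(p, p)
    D = p[:, None] + p[None, :] - P
    E = np.divide(P, D, out=np.zeros_like(P), where=D > 0)
    return J - E


def _mean_upper(C: np.ndarray) -> float:
    k = C.shape[0]
    iu = np.triu_indices(k, k=1)
    return float(C[iu].mean())


def raw_group_score(m: BinaryMatrix, cells: Sequence[str]) -> tuple[float, float]:
    """Mean pairwise centered similarity and mean per-cell 1-count for a group."""
    idx = m.cell_indices(list(cells))
    if len(idx) < 2:
        raise InputError("group must contain at least 2 cells")
    X = m.dense_columns(idx)
    s = X.sum(axis=0)
    if np.count_nonzero(s == 0) >= 2:
        warnings.warn(
            "group contains >= 2 all-zero cells; their pairwise similarity is 0",
            EpichaosWarning,
        )
    C = pairwise_centered_jaccard(X)
    return _mean_upper(C), float(s.mean())


# ---------------------------------------------------------------------------
# adjustment and finalisation
# ---------------------------------------------------------------------------

def adjust_scores(
    raw: Sequence[float], mean_count: Sequence[float]
) -> tuple[np.ndarray, bool]:
    """OLS residuals of raw ~ mean_count across the observations of one run.

    With fewer than 3 observations, or a constant covariate, the fit is
    degenerate (residuals would be identically zero and erase all
    signal); the documented fallback is plain mean-centering.  Returns
    ``(adjusted, used_fallback)``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    x = np.asarray(mean_count, dtype=np.float64)
    if raw.size == 0:
        raise InputError("no observations to adjust")
    if raw.size < 3 or np.ptp(x) == 0:
        return raw - raw.mean(), True
    xc = x - x.mean()
    slope = float(xc @ (raw - raw.mean()) / (xc @ xc))
    intercept = raw.mean() - slope * x.mean()
    return raw - (intercept + slope * x), False


def finalize_scores(adjusted: Sequence[float]) -> np.ndarray:
    """Min-max scale to [0, 1] and invert: 1 = most heterogeneous of the run."""
    adj = np.asarray(adjusted, dtype=np.float64)
    if adj.size == 0:
        raise InputError("no scores to finalize")
    lo, hi = adj.min(), adj.max()
    if hi == lo:
        warnings.warn(
            "all adjusted scores equal; final scores set to 0.5",
            DegenerateRunWarning,
        )
        return np.full(adj.shape, 0.5)
    return 1.0 - (adj - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# subsampling and orchestration
# ---------------------------------------------------------------------------

def _group_members(grouping: Mapping[str, str]) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for cell, group in grouping.items():
        members.setdefault(str(group), []).append(cell)
    # cell order within each group fixed by sorting: pair enumeration and
    # subsampling become independent of dict insertion order
    return {g: sorted(cs) for g, cs in sorted(members.items())}


def subsample_groups(
    grouping: Mapping[str, str],
    n_subsamples: int = 5,
    size: int = 100,
    seed: int = 0,
) -> list[Replicate]:
    """Replicate plan: n_subsamples draws of `size` cells per large group.

    Groups with at least ``size`` cells yield ``n_subsamples`` replicates
    sampled without replacement (independently across replicates);
    smaller groups yield a single replicate containing all their cells.
    """
    if size < 2:
        raise InputError("subsample size must be >= 2")
    if n_subsamples < 1:
        raise InputError("n_subsamples must be >= 1")
    rng = np.random.default_rng(seed)
    replicates: list[Replicate] = []
    for group, cells in _group_members(grouping).items():
        if len(cells) >= size:
            for r in range(n_subsamples):
                chosen = rng.choice(len(cells), size=size, replace=False)
                replicates.append(
                    Replicate(group, r, tuple(cells[i] for i in sorted(chosen)))
                )
        else:
            replicates.append(Replicate(group, 0, tuple(cells)))
    return replicates


def _score_replicates(
    m: BinaryMatrix, replicates: Sequence[Replicate]
) -> tuple[list[Replicate], list[dict]]:
    """Raw-score each replicate; skip (with a warning) groups below 2 cells."""
    scored: list[Replicate] = []
    rows: list[dict] = []
    for rep in replicates:
        if len(rep.cell_ids) < 2:
            warnings.warn(
                f"group {rep.group!r} has fewer than 2 cells; skipped",
                EpichaosWarning,
            )
            rows.append(
                dict(
                    group=rep.group,
                    replicate=rep.replicate,
                    n_cells=len(rep.cell_ids),
                    mean_count=np.nan,
                    raw=np.nan,
                    adjusted=np.nan,
                    epichaos=np.nan,
                    flags="skipped_too_small",
                )
            )
            continue
        raw, mean_count = raw_group_score(m, rep.cell_ids)
        scored.append(rep)
        rows.append(
            dict(
                group=rep.group,
                replicate=rep.replicate,
                n_cells=len(rep.cell_ids),
                mean_count=mean_count,
                raw=raw,
                adjusted=np.nan,
                epichaos=np.nan,
                flags=".",
            )
        )
    return scored, rows


def _assemble(rows: list[dict], adjusted: np.ndarray, final: np.ndarray, fallback: bool) -> pd.DataFrame:
    k = 0
    for row in rows:
        if row["flags"] == "skipped_too_small":
            continue
        row["adjusted"] = adjusted[k]
        row["epichaos"] = final[k]
        if fallback:
            row["flags"] = "adjust_fallback"
        k += 1
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def compute_epichaos(
    m: BinaryMatrix,
    grouping: Mapping[str, str],
    subsample: bool = True,
    n_subsamples: int = 5,
    size: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every group of cells; one output row per (group, replicate).

    Orchestrates subsampling, per-replicate raw scores, the count
    adjustment fitted across all replicates of the run, and the final
    min-max inversion.
    """
    m.cell_indices(list(grouping))
    if subsample:
        replicates = subsample_groups(grouping, n_subsamples, size, seed)
    else:
        replicates = [
            Replicate(g, 0, tuple(cs)) for g, cs in _group_members(grouping).items()
        ]
    scored, rows = _score_replicates(m, replicates)
    if not scored:
        raise InputError("no group with >= 2 cells; nothing to score")
    raw = [r["raw"] for r in rows if r["flags"] != "skipped_too_small"]
    mc = [r["mean_count"] for r in rows if r["flags"] != "skipped_too_small"]
    adjusted, fallback = adjust_scores(raw, mc)
    final = finalize_scores(adjusted)
    return _assemble(rows, adjusted, final, fallback)


def per_chromosome_scores(
    m: BinaryMatrix,
    features: pd.DataFrame,
    grouping: Mapping[str, str],
    min_features: int = 20,
    subsample: bool = True,
    n_subsamples: int = 5,
    size: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """CNA-robust variant: score and adjust per chromosome, then average.

    For every chromosome with at least ``min_features`` features, raw
    scores are computed on that chromosome's features only and adjusted
    against the chromosome-restricted mean count.  Each observation's
    corrected score is the mean of its per-chromosome residuals; the
    final 0-1 transform is applied to those means.  A whole-chromosome
    copy-number change then perturbs only one stratum's regression
    instead of the genome-wide covariate.
    """
    features = validate_feature_table(features, m.n_features)
    chroms = [
        c
        for c, cnt in features["chrom"].value_counts().items()
        if cnt >= min_features
    ]
    if not chroms:
        raise InputError(
            f"no chromosome with >= {min_features} features; cannot stratify"
        )
    chroms = sorted(chroms)
    m.cell_indices(list(grouping))
    if subsample:
        replicates = subsample_groups(grouping, n_subsamples, size, seed)
    else:
        replicates = [
            Replicate(g, 0, tuple(cs)) for g, cs in _group_members(grouping).items()
        ]
    replicates = [r for r in replicates if len(r.cell_ids) >= 2]
    if not replicates:
        raise InputError("no group with >= 2 cells; nothing to score")

    chrom_arr = features["chrom"].to_numpy()
    resid = np.zeros((len(replicates), len(chroms)))
    raws = np.zeros_like(resid)
    for j, chrom in enumerate(chroms):
        sub = m.subset_rows(chrom_arr == chrom)
        obs = [raw_group_score(sub, rep.cell_ids) for rep in replicates]
        raw_j = [o[0] for o in obs]
        mc_j = [o[1] for o in obs]
        adj_j, _ = adjust_scores(raw_j, mc_j)
        resid[:, j] = adj_j
        raws[:, j] = raw_j

    corrected = resid.mean(axis=1)
    final = finalize_scores(corrected)
    rows = []
    for i, rep in enumerate(replicates):
        idx = m.cell_indices(list(rep.cell_ids))
        X = m.dense_columns(idx)
        rows.append(
            dict(
                group=rep.group,
                replicate=rep.replicate,
                n_cells=len(rep.cell_ids),
                mean_count=float(X.sum(axis=0).mean()),
                raw=float(raws[i].mean()),
                adjusted=float(corrected[i]),
                epichaos=float(final[i]),
                flags="per_chromosome",
            )
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
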