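"""Synthetic binary-matrix generators for validation.

Every generator is a pure function of its parameters and a single
integer seed.  The default sizes (2000 features x 100 cells, density
0.5, 10 homogenized rows per step, marker probabilities 0.6/0.05) are
configuration knobs recorded in each series' ``params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import BinaryMatrix, InputError

__all__ = [
    "SyntheticSeries",
    "gen_controlled_series",
    "gen_perturbation_series",
    "gen_sparsity_series",
    "gen_celltype_mixtures",
    "gen_depth_series",
    "gen_cna_groups",
    "gen_flip_noise",
    "gen_archetype_matrix",
    "gen_count_matrix",
    "combine_series",
]


@dataclass
class SyntheticSeries:
    """An ordered list of equal-dimension matrices with known truth levels."""

    matrices: list[BinaryMatrix]
    truth: np.ndarray  # per-matrix controlled heterogeneity level
    names: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=np.float64)
        if not (len(self.matrices) == len(self.truth) == len(self.names)):
            raise InputError("matrices, truth and names must have equal length")
        shapes = {(m.n_features, m.n_cells) for m in self.matrices}
        if len(shapes) > 1:
            raise InputError(f"series matrices differ in shape: {shapes}")

    def __len__(self) -> int:
        return len(self.matrices)


def combine_series(series: SyntheticSeries) -> tuple[BinaryMatrix, dict[str, str]]:
    """Stack a series column-wise into one matrix plus a cell->dataset grouping.

    Cell barcodes are prefixed with the dataset name so they stay unique;
    the grouping maps each to its dataset, ready for joint scoring.
    """
    import scipy.sparse as sp

    blocks = [m.values for m in series.matrices]
    cell_ids: list[str] = []
    grouping: dict[str, str] = {}
    for name, m in zip(series.names, series.matrices):
        for c in m.cell_ids:
            cid = f"{name}|{c}"
            cell_ids.append(cid)
            grouping[cid] = name
    stacked = BinaryMatrix(
        sp.csr_matrix(sp.hstack(blocks)),
        series.matrices[0].feature_ids,
        np.asarray(cell_ids, dtype=object),
    )
    return stacked, grouping


def _bernoulli(rng: np.random.Generator, shape, p) -> np.ndarray:
    return (rng.random(shape) < p).astype(np.uint8)


def gen_archetype_matrix(
    n_features: int = 2000,
    n_cells: int = 100,
    density: float = 0.5,
    seed: int = 0,
) -> BinaryMatrix:
    """Fully homogeneous matrix: one Bernoulli(density) row pattern shared
    identically by every cell."""
    rng = np.random.default_rng(seed)
    pattern = _bernoulli(rng, n_features, density)
    return BinaryMatrix.from_dense(np.repeat(pattern[:, None], n_cells, axis=1))


# ---------------------------------------------------------------------------
# controlled heterogeneity series
# ---------------------------------------------------------------------------

def gen_controlled_series(
    n_steps: int = 100,
    n_features: int = 2000,
    n_cells: int = 100,
    density: float = 0.5,
    rows_per_step: int = 10,
    seed: int = 0,
) -> SyntheticSeries:
    """Series of matrices with decreasing heterogeneity at constant total count.

    Dataset 0 is i.i.d. Bernoulli(density).  Dataset i homogenizes
    ``i * rows_per_step`` donor rows (their 1's removed) and the same
    number of recipient rows (zero entries filled with the displaced 1's,
    saturating row by row), so the total 1-count is identical across the
    series while cell-to-cell variability shrinks.  Truth level for
    dataset i is ``(n_steps - i) / n_steps`` (1 = most heterogeneous).
    """
    if rows_per_step * n_steps * 2 > n_features:
        raise InputError(
            "need rows_per_step * n_steps * 2 <= n_features "
            f"({rows_per_step * n_steps * 2} > {n_features})"
        )
    rng = np.random.default_rng(seed)
    base = _bernoulli(rng, (n_features, n_cells), density)
    total = int(base.sum())

    perm = rng.permutation(n_features)
    donors = perm[: n_steps * rows_per_step]
    recipients = perm[n_steps * rows_per_step : 2 * n_steps * rows_per_step]
    extras = perm[2 * n_steps * rows_per_step :]

    matrices = []
    truth = []
    names = []
    for i in range(n_steps):
        mat = base.copy()
        d = donors[: i * rows_per_step]
        budget = int(mat[d].sum())
        mat[d] = 0
        # fill recipient rows to saturation until the displaced 1's run out
        candidates = list(recipients[: i * rows_per_step]) + list(extras) + list(
            recipients[i * rows_per_step :]
        )
        for r in candidates:
            if budget <= 0:
                break
            zeros = np.flatnonzero(mat[r] == 0)
            if zeros.size <= budget:
                mat[r] = 1
                budget -= zeros.size
            else:
                mat[r, zeros[:budget]] = 1
                budget = 0
        if budget > 0:
            raise InputError("displaced 1's exceed total recipient capacity")
        assert int(mat.sum()) == total
        matrices.append(BinaryMatrix.from_dense(mat))
        truth.append((n_steps - i) / n_steps)
        names.append(f"d{i:03d}")
    return SyntheticSeries(
        matrices,
        np.asarray(truth),
        names,
        params=dict(
            generator="controlled",
            n_steps=n_steps,
            n_features=n_features,
            n_cells=n_cells,
            density=density,
            rows_per_step=rows_per_step,
            seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# perturbation series
# ---------------------------------------------------------------------------

def gen_perturbation_series(
    base: BinaryMatrix,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    mode: str = "remove",
    seed: int = 0,
) -> SyntheticSeries:
    """Perturb a base matrix by randomly removing or adding 1's.

    ``remove`` sets ``floor(f * n_ones)`` randomly chosen 1-entries to 0;
    ``add`` sets the same number of randomly chosen 0-entries to 1.  Each
    fraction perturbs the pristine base independently; truth = fraction.
    """
    if mode not in ("add", "remove"):
        raise InputError(f"mode must be 'add' or 'remove', got {mode!r}")
    if any(not (0 < f < 1) for f in fractions):
        raise InputError("fractions must lie in (0, 1)")
    arr = base.dense()
    ones = np.flatnonzero(arr.ravel() == 1)
    zeros = np.flatnonzero(arr.ravel() == 0)
    if ones.size == 0:
        raise InputError("base matrix has no 1-entries")
    rng = np.random.default_rng(seed)
    matrices, names = [], []
    for f in fractions:
        k = int(np.floor(f * ones.size))
        flat = arr.ravel().copy()
        if mode == "remove":
            flat[rng.choice(ones, size=k, replace=False)] = 0
        else:
            if k > zeros.size:
                raise InputError(
                    f"add mode needs {k} zero entries but only {zeros.size} exist"
                )
            flat[rng.choice(zeros, size=k, replace=False)] = 1
        matrices.append(
            BinaryMatrix.from_dense(
                flat.reshape(arr.shape), base.feature_ids, base.cell_ids
            )
        )
        names.append(f"{mode}{int(round(100 * f)):02d}")
    return SyntheticSeries(
        matrices,
        np.asarray(fractions, dtype=float),
        names,
        params=dict(generator="perturb", mode=mode, fractions=list(fractions), seed=seed),
    )


# ---------------------------------------------------------------------------
# sparsity series
# ---------------------------------------------------------------------------

def gen_sparsity_series(
    n_datasets: int = 100,
    n_features: int = 2000,
    n_cells: int = 100,
    density_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> SyntheticSeries:
    """Pure-noise matrices of equal dimensions and linearly increasing density."""
    lo, hi = density_range
    if not (0 < lo < hi < 1):
        raise InputError("density_range must be increasing within (0, 1)")
    rng = np.random.default_rng(seed)
    densities = np.linspace(lo, hi, n_datasets)
    matrices = [
        BinaryMatrix.from_dense(_bernoulli(rng, (n_features, n_cells), d))
        for d in densities
    ]
    return SyntheticSeries(
        matrices,
        np.ones(n_datasets),  # identical true heterogeneity: all pure noise
        [f"s{i:03d}" for i in range(n_datasets)],
        params=dict(
            generator="sparsity",
            n_datasets=n_datasets,
            n_features=n_features,
            n_cells=n_cells,
            density_range=list(density_range),
            seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# cell-type mixtures
# ---------------------------------------------------------------------------

def gen_celltype_mixtures(
    n_types: int = 5,
    cells_per_type: int = 100,
    markers_per_type: int = 500,
    p_on_marker: float = 0.6,
    p_off: float = 0.05,
    seed: int = 0,
) -> SyntheticSeries:
    """In-silico mixtures of synthetic cell types over marker-block features.

    Each archetype is accessible with probability ``p_on_marker`` on its
    own marker block and ``p_off`` elsewhere.  One matrix is produced for
    every non-empty subset of the types; a k-type mixture draws cells as
    evenly as possible from its member types (``cells_per_type`` total).
    Truth = number of mixed types, scaled to (0, 1] by ``k / n_types``.
    """
    if n_types < 2:
        raise InputError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    n_features = n_types * markers_per_type
    probs = np.full((n_types, n_features), p_off)
    for t in range(n_types):
        probs[t, t * markers_per_type : (t + 1) * markers_per_type] = p_on_marker

    matrices, truth, names = [], [], []
    for k in range(1, n_types + 1):
        for combo in combinations(range(n_types), k):
            sizes = np.full(k, cells_per_type // k)
            sizes[: cells_per_type % k] += 1
            cols = []
            for t, sz in zip(combo, sizes):
                cols.append(_bernoulli(rng, (sz, n_features), probs[t]).T)
            matrices.append(BinaryMatrix.from_dense(np.hstack(cols)))
            truth.append(k / n_types)
            names.append("mix_" + "".join(str(t + 1) for t in combo))
    return SyntheticSeries(
        matrices,
        np.asarray(truth),
        names,
        params=dict(
            generator="mixture",
            n_types=n_types,
            cells_per_type=cells_per_type,
            markers_per_type=markers_per_type,
            p_on_marker=p_on_marker,
            p_off=p_off,
            seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# sequencing-depth series
# ---------------------------------------------------------------------------

def gen_count_matrix(
    n_features: int = 2000,
    n_cells: int = 500,
    mean_per_cell: float = 400.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic non-negative count matrix: Poisson draws around per-feature
    rates (log-normal across features) and mild per-cell depth variation."""
    rng = np.random.default_rng(seed)
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    rates = rates / rates.sum() * mean_per_cell
    depth = rng.lognormal(mean=0.0, sigma=0.2, size=n_cells)
    return rng.poisson(np.outer(rates, depth)).astype(np.int64)


def gen_depth_series(
    base_counts: np.ndarray,
    depths: Sequence[int] = (50000, 60000, 70000, 80000, 90000, 100000),
    seed: int = 0,
) -> SyntheticSeries:
    """Thin a base count matrix to fixed sequencing depths, then binarize.

    For each target depth D the base reads are subsampled without
    replacement (multivariate hypergeometric over matrix entries), so the
    realized total is exactly D and D = total reproduces the base.  This
    is a documented internal stand-in for read-level simulators: a
    behavioral, not bitwise, reproduction of depth variation.
    """
    base_counts = np.asarray(base_counts)
    if np.any(base_counts < 0) or not np.issubdtype(base_counts.dtype, np.integer):
        raise InputError("base counts must be non-negative integers")
    total = int(base_counts.sum())
    rng = np.random.default_rng(seed)
    flat = base_counts.ravel()
    matrices, names = [], []
    for d in depths:
        if d > total:
            raise InputError(f"depth {d} exceeds base total count {total}")
        thinned = rng.multivariate_hypergeometric(flat, int(d), method="marginals")
        matrices.append(
            BinaryMatrix.from_dense((thinned.reshape(base_counts.shape) > 0).astype(np.uint8))
        )
        names.append(f"depth{d}")
    return SyntheticSeries(
        matrices,
        np.asarray(depths, dtype=float),
        names,
        params=dict(generator="depth", depths=[int(d) for d in depths], seed=seed),
    )


# ---------------------------------------------------------------------------
# copy-number alteration groups
# ---------------------------------------------------------------------------

def gen_cna_groups(
    n_groups: int = 6,
    cells_per_group: int = 100,
    chrom_labels: Sequence[str] = tuple(f"chr{i}" for i in range(1, 11)),
    features_per_chrom: int = 200,
    cna_type: str = "deletion",
    target_chrom: str = "chr10",
    seed: int = 0,
) -> tuple[BinaryMatrix, dict[str, str], pd.DataFrame]:
    """Groups of cells from one archetype, one carrying a whole-chromosome CNA.

    All groups sample cells i.i.d. Bernoulli around a shared per-feature
    accessibility profile.  In the last group (labelled ``cna``) the
    features of ``target_chrom`` are zeroed (deletion) or have their
    accessibility probability doubled, capped at 1 (gain).  Returns the
    stacked matrix, the cell grouping, and the feature coordinate table.
    """
    if cna_type not in ("gain", "deletion"):
        raise InputError(f"cna_type must be 'gain' or 'deletion', got {cna_type!r}")
    if target_chrom not in chrom_labels:
        raise InputError(f"target_chrom {target_chrom!r} not in chrom_labels")
    rng = np.random.default_rng(seed)
    n_features = len(chrom_labels) * features_per_chrom
    probs = rng.uniform(0.2, 0.8, size=n_features)
    chrom = np.repeat(np.asarray(chrom_labels, dtype=object), features_per_chrom)
    on_target = chrom == target_chrom

    blocks, grouping, cell_ids = [], {}, []
    for g in range(n_groups):
        label = "cna" if g == n_groups - 1 else f"g{g}"
        p = probs.copy()
        if label == "cna":
            if cna_type == "deletion":
                p[on_target] = 0.0
            else:
                p[on_target] = np.minimum(1.0, 2.0 * p[on_target])
        blocks.append(_bernoulli(rng, (cells_per_group, n_features), p).T)
        for j in range(cells_per_group):
            cid = f"{label}|c{j}"
            cell_ids.append(cid)
            grouping[cid] = label

    m = BinaryMatrix.from_dense(np.hstack(blocks), cell_ids=cell_ids)
    starts = np.tile(np.arange(features_per_chrom) * 1000, len(chrom_labels))
    features = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + 500}
    )
    return m, grouping, features


def gen_flip_noise(base: BinaryMatrix, rate: float, seed: int = 0) -> BinaryMatrix:
    """Flip every entry independently with the given probability."""
    if not (0 <= rate < 1):
        raise InputError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = base.dense()
    flips = rng.random(arr.shape) < rate
    return BinaryMatrix.from_dense(
        np.where(flips, 1 - arr, arr).astype(np.uint8), base.feature_ids, base.cell_ids
    )
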