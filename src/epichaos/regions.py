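"""Region-set analysis: subset a peaks-by-cells matrix by genomic
interval sets (TFBS collections, gene-set promoters), score each set
within a cell group, and rank sets across cell types.

All interval arithmetic is 0-based half-open; a feature is retained if
it overlaps any interval of the set by at least one base pair.  Strand
is ignored.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import adjust_scores, finalize_scores, raw_group_score
from .types import BinaryMatrix, EpichaosError, InputError, RegionSet, validate_feature_table

__all__ = [
    "overlap_mask",
    "overlap_subset",
    "score_region_sets",
    "promoters_for_gene_sets",
    "rank_across_celltypes",
]

logger = logging.getLogger(__name__)

REGION_COLUMNS = [
    "region_set",
    "n_overlapping_features",
    "mean_count",
    "raw",
    "adjusted",
    "epichaos",
    "rank",
    "flags",
]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def overlap_mask(features: pd.DataFrame, rs: RegionSet) -> np.ndarray:
    """Boolean mask over matrix features: >= 1 bp overlap with any interval."""
    mask = np.zeros(len(features), dtype=bool)
    f_chrom = features["chrom"].to_numpy()
    f_start = features["start"].to_numpy(dtype=np.int64)
    f_end = features["end"].to_numpy(dtype=np.int64)
    for chrom, sub in rs.intervals.groupby("chrom", sort=False):
        sel = np.flatnonzero(f_chrom == chrom)
        if sel.size == 0:
            continue
        ms, me = _merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        # feature [fs, fe) overlaps merged interval i iff fs < me[i] and ms[i] < fe;
        # with disjoint sorted intervals the candidate is the first with me > fs
        pos = np.searchsorted(me, f_start[sel], side="right")
        hit = (pos < len(ms)) & (ms[np.minimum(pos, len(ms) - 1)] < f_end[sel])
        mask[sel[hit]] = True
    return mask


def overlap_subset(m: BinaryMatrix, features: pd.DataFrame, rs: RegionSet) -> BinaryMatrix:
    """Retain exactly the features overlapping the region set; cells unchanged."""
    features = validate_feature_table(features, m.n_features)
    mask = overlap_mask(features, rs)
    return m.subset_rows(mask)


def score_region_sets(
    m: BinaryMatrix,
    features: pd.DataFrame,
    cells: Sequence[str],
    collection: Sequence[RegionSet],
    min_features: int = 20,
) -> pd.DataFrame:
    """Score one cell group on every region set of a collection.

    The count adjustment is fitted across region sets (the covariate is
    the mean per-cell 1-count within each subset), and the 0-1 transform
    spans the collection.  Sets retaining fewer than ``min_features``
    features are flagged and excluded from scaling and ranking.
    """
    features = validate_feature_table(features, m.n_features)
    names = [rs.name for rs in collection]
    if len(set(names)) != len(names):
        raise InputError("region set names must be unique within a collection")

    rows = []
    qualifying = []
    for rs in collection:
        mask = overlap_mask(features, rs)
        n_overlap = int(mask.sum())
        if n_overlap < min_features:
            rows.append(
                dict(
                    region_set=rs.name,
                    n_overlapping_features=n_overlap,
                    mean_count=np.nan,
                    raw=np.nan,
                    adjusted=np.nan,
                    epichaos=np.nan,
                    rank=np.nan,
                    flags="below_min_features",
                )
            )
            continue
        sub = m.subset_rows(mask)
        raw, mean_count = raw_group_score(sub, cells)
        qualifying.append(len(rows))
        rows.append(
            dict(
                region_set=rs.name,
                n_overlapping_features=n_overlap,
                mean_count=mean_count,
                raw=raw,
                adjusted=np.nan,
                epichaos=np.nan,
                rank=np.nan,
                flags=".",
            )
        )
    if len(qualifying) < 2:
        raise EpichaosError(
            f"fewer than 2 region sets retain >= {min_features} features"
        )
    raw_v = [rows[i]["raw"] for i in qualifying]
    mc_v = [rows[i]["mean_count"] for i in qualifying]
    adjusted, fallback = adjust_scores(raw_v, mc_v)
    final = finalize_scores(adjusted)
    for k, i in enumerate(qualifying):
        rows[i]["adjusted"] = adjusted[k]
        rows[i]["epichaos"] = final[k]
        if fallback:
            rows[i]["flags"] = "adjust_fallback"
    # dense ranks on the final score, 1 = most heterogeneous
    finals = np.array([rows[i]["epichaos"] for i in qualifying])
    uniq = np.unique(finals)[::-1]
    dense = {v: r + 1 for r, v in enumerate(uniq)}
    for k, i in enumerate(qualifying):
        rows[i]["rank"] = dense[finals[k]]
    df = pd.DataFrame(rows, columns=REGION_COLUMNS)
    # deterministic presentation: by rank then name; flagged rows last
    df = df.sort_values(
        ["rank", "region_set"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    return df


def promoters_for_gene_sets(
    promoters: pd.DataFrame, gene_sets: Mapping[str, Sequence[str]]
) -> list[RegionSet]:
    """Build one RegionSet of promoter intervals per gene set.

    ``promoters`` maps gene id -> interval: a DataFrame indexed by gene
    with chrom/start/end columns.  Genes absent from the table are
    counted and logged; duplicate genes within a set are de-duplicated.
    """
    for col in ("chrom", "start", "end"):
        if col not in promoters.columns:
            raise InputError(f"promoter table missing column {col!r}")
    if promoters.index.has_duplicates:
        raise InputError("promoter table must have one interval per gene id")
    out = []
    for name, genes in gene_sets.items():
        uniq = sorted(set(genes))
        present = [g for g in uniq if g in promoters.index]
        missing = len(uniq) - len(present)
        if missing:
            logger.info(
                "gene set %s: %d/%d genes missing from promoter table",
                name,
                missing,
                len(uniq),
            )
        ivals = promoters.loc[present, ["chrom", "start", "end"]]
        if len(present) == 0:
            logger.info("gene set %s: empty region set (no promoter matches)", name)
            out.append(RegionSet(name, pd.DataFrame(columns=["chrom", "start", "end"])))
        else:
            out.append(RegionSet(name, ivals))
    return out


def rank_across_celltypes(
    tables: Mapping[str, pd.DataFrame], target_set: str
) -> dict[str, int]:
    """Rank of one region set (1 = most heterogeneous) in each group's table."""
    ranks = {}
    for group, table in tables.items():
        row = table.loc[table["region_set"] == target_set]
        if row.empty:
            raise EpichaosError(
                f"region set {target_set!r} absent from table for group {group!r}"
            )
        rank = row["rank"].iloc[0]
        if pd.isna(rank):
            raise EpichaosError(
                f"region set {target_set!r} not ranked (flagged) in group {group!r}"
            )
        ranks[group] = int(rank)
    return ranks
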