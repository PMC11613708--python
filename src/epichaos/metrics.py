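"""Orthogonal heterogeneity measures used for cross-modality validation:
per-gene transcriptional noise and per-CpG methylation variance
aggregated over region sets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import InputError, RegionSet

__all__ = ["transcriptional_noise_cv", "methylation_region_variability"]


def transcriptional_noise_cv(expr) -> pd.Series:
    """Coefficient of variation per gene (sample sd / mean over cells).

    ``expr`` is a genes x cells non-negative matrix (DataFrame or array).
    Genes with mean 0 are undefined and returned as missing.  CV is
    scale-invariant per gene; the sample (n-1) convention is used.
    """
    if isinstance(expr, pd.DataFrame):
        index = expr.index
        arr = expr.to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(expr, dtype=np.float64)
        index = pd.RangeIndex(arr.shape[0])
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InputError("expression matrix must be genes x cells with >= 2 cells")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise InputError("expression values must be finite and non-negative")
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.Series(cv, index=index, name="cv")


def methylation_region_variability(
    values: pd.DataFrame,
    sites: pd.DataFrame,
    region_sets: Sequence[RegionSet],
    missing_quantile: float = 0.005,
    scale: bool = False,
) -> pd.Series:
    """Mean per-CpG variance over each region set's sites.

    ``values`` is sites x samples in [0, 1] with NaN for missing;
    ``sites`` carries one (chrom, pos) row per site.  Sites whose missing
    fraction exceeds the ``missing_quantile`` quantile of the per-site
    missingness distribution are removed; per remaining site the sample
    variance is taken over available values (pairwise-available policy),
    and per region set the mean variance over the sites falling inside
    its intervals (position within half-open interval) is reported.
    ``scale=True`` min-max scales the resulting vector to [0, 1].
    """
    arr = values.to_numpy(dtype=np.float64) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InputError("methylation matrix must be sites x samples with >= 2 samples")
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise InputError("methylation values must lie in [0, 1] (or be missing)")
    for col in ("chrom", "pos"):
        if col not in sites.columns:
            raise InputError(f"site table missing column {col!r}")
    if len(sites) != arr.shape[0]:
        raise InputError("site table and value matrix disagree on the number of sites")

    missing_frac = np.mean(~np.isfinite(arr), axis=1)
    threshold = np.quantile(missing_frac, missing_quantile)
    keep = missing_frac <= threshold

    with np.errstate(invalid="ignore"):
        variance = _nanvar(arr)
    variance[~keep] = np.nan

    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy(dtype=np.int64)
    out = {}
    for rs in region_sets:
        in_set = np.zeros(len(sites), dtype=bool)
        for _, row in rs.intervals.iterrows():
            in_set |= (chrom == row["chrom"]) & (pos >= row["start"]) & (pos < row["end"])
        vals = variance[in_set]
        vals = vals[np.isfinite(vals)]
        out[rs.name] = float(vals.mean()) if vals.size else np.nan
    result = pd.Series(out, name="mean_variance")
    if scale:
        lo, hi = result.min(), result.max()
        if np.isfinite(lo) and hi > lo:
            result = (result - lo) / (hi - lo)
    return result


def _nanvar(arr: np.ndarray) -> np.ndarray:
    """Row-wise sample variance over available values; NaN below 2 values."""
    n = np.isfinite(arr).sum(axis=1)
    out = np.full(arr.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        sub = arr[ok]
        mean = np.nanmean(sub, axis=1, keepdims=True)
        ss = np.nansum((sub - mean) ** 2, axis=1)
        out[ok] = ss / (n[ok] - 1)
    return out
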