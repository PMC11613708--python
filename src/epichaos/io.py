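"""Readers and writers for the package's on-disk formats.

Conventions: TSV everywhere with a mandatory header row, UTF-8, "." for
missing values; genomic coordinates 0-based half-open (BED); floats
written with 6 significant digits.  Matrices travel as a MatrixMarket
triplet (``matrix.mtx`` + ``features.tsv``/``features.bed`` +
``barcodes.tsv``) or as a dense TSV whose row index encodes coordinates
as ``chrom:start-end``.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import binarize
from .types import BinaryMatrix, InputError, RegionSet

__all__ = [
    "read_matrix",
    "write_matrix_dir",
    "read_grouping",
    "read_regions",
    "read_gmt",
    "read_promoters_bed",
    "read_methylation_tsv",
    "feature_table_from_ids",
    "write_table",
    "write_metadata",
    "config_hash",
]

_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def feature_table_from_ids(ids: Sequence[str]) -> pd.DataFrame | None:
    """Parse ``chr1:100-200``-style ids into a chrom/start/end table.

    Returns None when the ids do not follow the coordinate convention.
    """
    rows = []
    for i in ids:
        mobj = _COORD_RE.match(str(i))
        if mobj is None:
            return None
        start, end = int(mobj["start"]), int(mobj["end"])
        if start >= end:
            raise InputError(f"malformed feature coordinates {i!r}: start >= end")
        rows.append((mobj["chrom"], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _read_feature_file(path: Path) -> tuple[np.ndarray, pd.DataFrame | None]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] >= 3 and df[1].str.fullmatch(r"\d+").all():
        chrom = df[0]
        start = df[1].astype(np.int64)
        end = df[2].astype(np.int64)
        if (start >= end).any():
            i = int((start >= end).idxmax())
            raise InputError(f"{path}: feature line {i + 1}: start >= end")
        if df.shape[1] >= 4:
            ids = df[3].to_numpy(dtype=object)
        else:
            ids = np.array(
                [f"{c}:{s}-{e}" for c, s, e in zip(chrom, start, end)], dtype=object
            )
        table = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
        return ids, table
    ids = df[0].to_numpy(dtype=object)
    return ids, feature_table_from_ids(ids)


def _check_unique(ids: np.ndarray, what: str, path: Path) -> None:
    ser = pd.Series(ids)
    dup = ser[ser.duplicated()]
    if not dup.empty:
        raise InputError(f"{path}: duplicate {what}: {dup.iloc[0]!r}")


def read_matrix(
    path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    binarized: bool = True,
) -> tuple[BinaryMatrix, pd.DataFrame | None]:
    """Read a matrix from an MTX triplet directory/file or a dense TSV.

    ``path`` may be a directory holding ``matrix.mtx`` plus feature and
    barcode files, an ``.mtx`` file (with explicit companion paths), or a
    ``.tsv`` dense matrix with feature ids as the first column and cell
    barcodes as the header.  Counts are binarized when ``binarized``.
    Returns the matrix and the feature coordinate table when available.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise InputError(f"{path}: no matrix.mtx in directory")
        if features_path is None:
            for cand in ("features.bed", "features.tsv", "peaks.bed"):
                if (path / cand).exists():
                    features_path = path / cand
                    break
        if barcodes_path is None and (path / "barcodes.tsv").exists():
            barcodes_path = path / "barcodes.tsv"
        path = mtx

    if path.suffix == ".mtx":
        if features_path is None or barcodes_path is None:
            raise InputError("MTX input needs features and barcodes files")
        mat = sp.csr_matrix(scipy.io.mmread(path))
        feature_ids, ftable = _read_feature_file(Path(features_path))
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].to_numpy(dtype=object)
        _check_unique(feature_ids, "feature id", Path(features_path))
        _check_unique(barcodes, "barcode", Path(barcodes_path))
        if mat.shape != (len(feature_ids), len(barcodes)):
            raise InputError(
                f"dimension mismatch: matrix {mat.shape} vs "
                f"{len(feature_ids)} features x {len(barcodes)} barcodes"
            )
        if binarized:
            m = binarize(mat, feature_ids, barcodes)
        else:
            m = BinaryMatrix(sp.csr_matrix(mat, dtype=np.uint8), feature_ids, barcodes)
        return m, ftable

    # dense TSV
    df = pd.read_csv(path, sep="\t", index_col=0)
    feature_ids = df.index.to_numpy(dtype=object)
    barcodes = df.columns.to_numpy(dtype=object)
    _check_unique(feature_ids, "feature id", path)
    _check_unique(barcodes, "barcode", path)
    arr = df.to_numpy()
    m = binarize(arr, feature_ids, barcodes) if binarized else BinaryMatrix.from_dense(arr, feature_ids, barcodes)
    return m, feature_table_from_ids(feature_ids)


def write_matrix_dir(
    out_dir: str | Path,
    m: BinaryMatrix,
    features: pd.DataFrame | None = None,
    grouping: Mapping[str, str] | None = None,
    metadata: Mapping | None = None,
) -> Path:
    """Write an MTX triplet (plus optional grouping and metadata) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", m.values.tocoo(), field="integer")
    if features is not None:
        pd.DataFrame(
            {
                "chrom": features["chrom"],
                "start": features["start"],
                "end": features["end"],
                "name": m.feature_ids,
            }
        ).to_csv(out / "features.bed", sep="\t", header=False, index=False)
    else:
        pd.Series(m.feature_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    if grouping is not None:
        pd.DataFrame(
            {"cell_id": list(grouping), "group": [grouping[c] for c in grouping]}
        ).to_csv(out / "grouping.tsv", sep="\t", index=False)
    if metadata is not None:
        write_metadata(out / "metadata.json", metadata)
    return out


def read_grouping(path: str | Path) -> dict[str, str]:
    """TSV with columns cell_id, group -> mapping (duplicates rejected)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "group"):
        if col not in df.columns:
            raise InputError(f"{path}: grouping file missing column {col!r}")
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if not dup.empty:
        raise InputError(f"{path}: duplicate cell_id {dup.iloc[0]!r}")
    return dict(zip(df["cell_id"], df["group"]))


def _parse_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise InputError(f"{path}:{lineno}: invalid interval (start >= end)")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else None))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_regions(path: str | Path) -> list[RegionSet]:
    """One RegionSet per BED file (name = file stem); directories are globbed."""
    path = Path(path)
    if path.is_dir():
        beds = sorted(path.glob("*.bed"))
        if not beds:
            raise InputError(f"{path}: no .bed files found")
        return [RegionSet(p.stem, _parse_bed(p)[["chrom", "start", "end"]]) for p in beds]
    return [RegionSet(path.stem, _parse_bed(path)[["chrom", "start", "end"]])]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            if parts[0] in sets:
                raise InputError(f"{path}:{lineno}: duplicate gene set {parts[0]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_promoters_bed(path: str | Path) -> pd.DataFrame:
    """Promoter BED with 4th column = gene id -> gene-indexed interval table."""
    df = _parse_bed(Path(path))
    if df["name"].isna().any():
        raise InputError(f"{path}: promoter BED needs a 4th (gene id) column")
    if df["name"].duplicated().any():
        dup = df["name"][df["name"].duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate promoter entry for gene {dup!r}")
    return df.set_index("name")[["chrom", "start", "end"]]


def read_methylation_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Methylation TSV (chrom, pos, one column per sample; empty/'.' = missing).

    Returns (values sites x samples, site coordinate table).
    """
    df = pd.read_csv(path, sep="\t", na_values=["."])
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise InputError(f"{path}: methylation file missing column {col!r}")
    sites = df[["chrom", "pos"]].copy()
    values = df.drop(columns=["chrom", "pos"]).astype(np.float64)
    return values, sites


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with header, '.' for missing, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep=".")


def config_hash(config: Mapping) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_metadata(path: str | Path, config: Mapping) -> None:
    meta = dict(config)
    meta["config_hash"] = config_hash(config)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
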