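"""Readers and writers for the file formats the pipeline touches.

All tabular data are held in pandas DataFrames with a single internal
coordinate convention: 0-based positions, half-open intervals.  Only the
Bismark-coverage reader shifts coordinates (its positions are 1-based);
BED coordinates pass through unchanged.

Canonical column layouts
------------------------
methylation calls : ``chrom, pos, strand, n_meth, n_unmeth``
intervals         : ``chrom, start, end, name``
fragments         : ``chrom, start, end``
classified sites  : calls + ``depth, fraction, meth_class`` and optionally
                    ``cell_type, generation``

The methylation-percentage column of a coverage file is never trusted:
fractions are always recomputed from the integer counts, which are the
primary data.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]
INTERVAL_COLUMNS = ["chrom", "start", "end", "name"]

#: deterministic column order for classified-site / marker tables
SITE_TABLE_COLUMNS = [
    "chrom", "pos", "strand", "depth", "n_meth", "n_unmeth",
    "fraction", "meth_class", "cell_type", "generation",
]


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line."""


def _compression(path) -> str | None:
    return "gzip" if str(path).endswith(".gz") else None


def read_methylation_calls(path) -> pd.DataFrame:
    """Read a Bismark coverage file into a calls DataFrame.

    The expected dialect is tab-separated
    ``chrom, start(1-based), end(1-based), methylation%, count_methylated,
    count_unmethylated`` with an optional seventh strand column
    (``+``/``-``; absent means ``+``).  Positions are shifted to 0-based.
    Files ending in ``.gz`` are decompressed transparently.

    Raises
    ------
    ParseError
        On non-integer counts, ``start > end``, a bad strand symbol or a
        duplicated ``(chrom, pos, strand)`` key; the message cites the
        1-based line number.  A methylation% inconsistent with the counts
        only triggers a warning — counts win.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, dtype=str,
            compression=_compression(path), skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CALL_COLUMNS, [str, np.int64, str, np.int64, np.int64])})
    if raw.shape[1] not in (6, 7):
        raise ParseError(
            f"{path}: expected 6 or 7 tab-separated columns, found {raw.shape[1]}")

    def _int_col(i: int, what: str) -> np.ndarray:
        vals = pd.to_numeric(raw[i], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: line {line}: non-integer {what} "
                             f"{raw[i].iloc[line - 1]!r}")
        return vals.to_numpy(dtype=np.int64)

    start = _int_col(0 + 1, "start coordinate")
    end = _int_col(2, "end coordinate")
    bad = start > end
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ParseError(f"{path}: line {line}: start > end")
    n_meth = _int_col(4, "methylated count")
    n_unmeth = _int_col(5, "unmethylated count")
    if (n_meth < 0).any() or (n_unmeth < 0).any():
        line = int(np.flatnonzero((n_meth < 0) | (n_unmeth < 0))[0]) + 1
        raise ParseError(f"{path}: line {line}: negative read count")

    if raw.shape[1] == 7:
        strand = raw[6].to_numpy(dtype=object)
        bad = ~np.isin(strand, ["+", "-"])
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ParseError(f"{path}: line {line}: bad strand {strand[line - 1]!r}")
    else:
        strand = np.full(len(raw), "+", dtype=object)

    pct = pd.to_numeric(raw[3], errors="coerce").to_numpy(dtype=float)
    depth = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = np.where(depth > 0, 100.0 * n_meth / np.maximum(depth, 1), np.nan)
    mismatch = np.isfinite(pct) & np.isfinite(implied) & (np.abs(pct - implied) > 0.5)
    if mismatch.any():
        warnings.warn(
            f"{path}: methylation%% column disagrees with counts on "
            f"{int(mismatch.sum())} row(s); counts take precedence",
            stacklevel=2)

    df = pd.DataFrame({
        "chrom": raw[0].to_numpy(dtype=object),
        "pos": start - 1,
        "strand": strand,
        "n_meth": n_meth,
        "n_unmeth": n_unmeth,
    })
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: duplicate site "
                         f"({df.chrom.iloc[line - 1]}, {df.pos.iloc[line - 1]})")
    return df


def write_methylation_calls(calls: pd.DataFrame, path) -> None:
    """Write calls in the 6-column Bismark coverage dialect (1-based)."""
    depth = calls["n_meth"] + calls["n_unmeth"]
    if (depth <= 0).any():
        raise ValueError("coverage rows require depth >= 1")
    out = pd.DataFrame({
        0: calls["chrom"],
        1: calls["pos"] + 1,
        2: calls["pos"] + 1,
        3: (100.0 * calls["n_meth"] / depth).map(lambda x: f"{x:.10g}"),
        4: calls["n_meth"],
        5: calls["n_unmeth"],
    })
    if (calls["strand"] != "+").any():
        out[6] = calls["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_intervals(path, *, named: bool = True) -> pd.DataFrame:
    """Read a BED3/BED6 file; coordinates pass through unchanged (0-based,
    half-open).  ``track``/``browser``/``#`` lines are skipped.  Rows with
    ``start >= end`` are rejected with a :class:`ParseError`.
    """
    rows = []
    opener = __import__("gzip").open if _compression(path) else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    if not named:
        df = df.drop(columns=["name"])
    return df.astype({"start": np.int64, "end": np.int64}, errors="ignore")


def read_fragments(path) -> pd.DataFrame:
    """Read paired-end fragment intervals from BED; columns chrom/start/end."""
    return read_intervals(path, named=False)


def write_intervals(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in INTERVAL_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_site_table(sites: pd.DataFrame, path, *, header: bool = True) -> None:
    """Write classified sites (or marker records) as a deterministic TSV.

    Column order follows :data:`SITE_TABLE_COLUMNS` (absent optional columns
    are dropped); rows are sorted by ``(chrom, pos, strand)``.  The header
    line is prefixed ``#`` and can be suppressed.  Re-reading with
    :func:`read_site_table` reproduces the input exactly (the fraction is
    recomputed from the integer counts rather than parsed).
    """
    cols = [c for c in SITE_TABLE_COLUMNS if c in sites.columns]
    extra = [c for c in sites.columns if c not in cols]
    df = sites[cols + extra].sort_values(
        ["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    out = df.copy()
    if "fraction" in out.columns:
        out["fraction"] = out["fraction"].map(lambda x: f"{x:.10g}")
    with open(path, "w") as fh:
        if header:
            fh.write("#" + "\t".join(df.columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_site_table(path) -> pd.DataFrame:
    """Inverse of :func:`write_site_table` (requires the ``#`` header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ParseError(f"{path}: missing '#'-prefixed header line")
        columns = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=columns)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in columns})
    for c in ("pos", "depth", "n_meth", "n_unmeth"):
        if c in df.columns:
            df[c] = df[c].astype(np.int64)
    if {"n_meth", "depth"} <= set(df.columns):
        df["fraction"] = df["n_meth"] / df["depth"]
    for c in ("chrom", "strand", "meth_class"):
        if c in df.columns:
            df[c] = df[c].astype(object)
    return df


def write_sites_bed(sites: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Write per-site BED (pos, pos+1) for classified/stable/marker sites."""
    out = pd.DataFrame({
        0: sites["chrom"],
        1: sites["pos"],
        2: sites["pos"] + 1,
    })
    if name_col is not None and name_col in sites.columns:
        out[3] = sites[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)
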