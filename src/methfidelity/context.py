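"""Genomic-context analyses around CpG islands and annotated features.

The central tool is a signed-offset metaplot around CGI borders: every
site (or MNase fragment midpoint) is assigned to its nearest CGI border
within a +/-window, with positive offsets inside the island and negative
offsets outside, then binned.  Enrichment profiles normalize a foreground
site set (e.g. stably fully methylated sites) against a background of all
depth-passing sites, which cancels the strongly non-uniform CpG coverage
of RRBS near islands; nucleosome occupancy profiles are mean-normalized
fragment-midpoint counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .classify import KEY

DEFAULT_WINDOW = 1500
DEFAULT_BIN_WIDTH = 50


@dataclass
class BorderProfile:
    """Binned signed-offset profile around CGI borders.

    ``bin_edges`` has length ``n_bins + 1`` spanning [-window, +window];
    positive offsets lie inside the island.  ``values`` holds the per-bin
    enrichment fold (or mean-normalized occupancy); bins with zero
    background are undefined and carry NaN, never zero.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    n_fg: np.ndarray
    n_bg: np.ndarray
    window: int = DEFAULT_WINDOW
    bin_width: int = DEFAULT_BIN_WIDTH

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset_bin_start": self.bin_edges[:-1].astype(int),
            "offset_bin_end": self.bin_edges[1:].astype(int),
            "value": self.values,
            "n_fg": self.n_fg,
            "n_bg": self.n_bg,
        })

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.to_frame().columns) + "\n")
            self.to_frame().to_csv(fh, sep="\t", header=False, index=False,
                                   float_format="%.10g")


def signed_border_offset(pos: int, start: int, end: int,
                         window: int | None = None) -> int | None:
    """Signed distance from ``pos`` to the nearest border of one island.

    The two borders sit at ``start`` and ``end - 1``; the nearer one is
    chosen (tie -> left).  The offset is the distance to that border,
    positive when ``pos`` lies inside [start, end), negative outside, and
    None when a window is given and the magnitude exceeds it.
    """
    d_left = abs(pos - start)
    d_right = abs((end - 1) - pos)
    dist = d_left if d_left <= d_right else d_right
    offset = dist if start <= pos < end else -dist
    if window is not None and dist > window:
        return None
    return offset


def _border_arrays(cgis: pd.DataFrame, chrom: str):
    sub = cgis[cgis["chrom"] == chrom]
    if len(sub) == 0:
        return None
    starts = sub["start"].to_numpy(np.int64)
    ends = sub["end"].to_numpy(np.int64)
    bpos = np.concatenate([starts, ends - 1])
    side = np.concatenate([np.zeros(len(sub)), np.ones(len(sub))])
    cstart = np.concatenate([starts, starts])
    cend = np.concatenate([ends, ends])
    order = np.lexsort((cend, cstart, side, bpos))
    return bpos[order], cstart[order], cend[order]


def assign_border_offsets(positions: pd.DataFrame, cgis: pd.DataFrame,
                          window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Nearest-border signed offsets for many sites against many islands.

    Ties are broken deterministically: smallest absolute distance, then
    smallest border coordinate, then left border before right.  Returns a
    float array aligned with ``positions`` rows; NaN marks sites farther
    than ``window`` from every border (or on a chromosome without islands).
    """
    out = np.full(len(positions), np.nan)
    pos_all = positions["pos"].to_numpy(np.int64)
    chroms = positions["chrom"].to_numpy(object)
    for chrom in pd.unique(chroms):
        arrays = _border_arrays(cgis, chrom)
        if arrays is None:
            continue
        bpos, cstart, cend = arrays
        idx = np.flatnonzero(chroms == chrom)
        pos = pos_all[idx]
        chunk = max(1, int(5e6) // max(1, len(bpos)))
        for lo in range(0, len(pos), chunk):
            p = pos[lo:lo + chunk]
            d = np.abs(p[:, None] - bpos[None, :])
            j = np.argmin(d, axis=1)  # first minimum = canonical tie-break
            dist = d[np.arange(len(p)), j]
            inside = (cstart[j] <= p) & (p < cend[j])
            off = np.where(inside, dist, -dist).astype(float)
            off[dist > window] = np.nan
            out[idx[lo:lo + chunk]] = off
    return out


def _bin_offsets(offsets: np.ndarray, window: int, bin_width: int) -> np.ndarray:
    if window % bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    n_bins = 2 * window // bin_width
    o = offsets[~np.isnan(offsets)]
    idx = np.floor((o + window) / bin_width).astype(int)
    idx[idx == n_bins] = n_bins - 1  # fold the +window edge into the last bin
    return np.bincount(idx, minlength=n_bins)


def _bin_edges(window: int, bin_width: int) -> np.ndarray:
    return np.arange(-window, window + bin_width, bin_width, dtype=float)


def _subset_check(fg: pd.DataFrame, bg: pd.DataFrame) -> None:
    key = [k for k in KEY if k in fg.columns and k in bg.columns] or ["chrom", "pos"]
    fg_keys = set(map(tuple, fg[key].itertuples(index=False)))
    bg_keys = set(map(tuple, bg[key].itertuples(index=False)))
    if not fg_keys <= bg_keys:
        raise ValueError("foreground sites must be a subset of the background")


def _cgis_with_fg(cgis: pd.DataFrame, fg: pd.DataFrame) -> pd.DataFrame:
    trees = _trees(cgis)
    keep = np.zeros(len(cgis), dtype=bool)
    lookup = {}
    for i, (chrom, start, end) in enumerate(
            cgis[["chrom", "start", "end"]].itertuples(index=False)):
        lookup.setdefault(chrom, []).append((start, end, i))
    for chrom, pos in fg[["chrom", "pos"]].itertuples(index=False):
        for start, end, i in lookup.get(chrom, ()):
            if start <= pos < end:
                keep[i] = True
    return cgis[keep].reset_index(drop=True)


def border_enrichment_profile(fg_sites: pd.DataFrame, bg_sites: pd.DataFrame,
                              cgis: pd.DataFrame,
                              window: int = DEFAULT_WINDOW,
                              bin_width: int = DEFAULT_BIN_WIDTH,
                              restrict_to_fg_cgis: bool = True) -> BorderProfile:
    """Foreground/background fold-enrichment profile around CGI borders.

    Each site within ``window`` of its nearest border contributes to one
    offset bin; per bin the fold is the foreground share divided by the
    background share, ``(n_fg/sum n_fg) / (n_bg/sum n_bg)``.  By default
    only islands containing at least one foreground site are profiled.
    The foreground must be a subset of the background (which should be all
    depth-passing classified sites, cancelling RRBS coverage bias).
    """
    if len(fg_sites) == 0 or len(bg_sites) == 0:
        raise ValueError("foreground and background must be non-empty")
    _subset_check(fg_sites, bg_sites)
    use_cgis = _cgis_with_fg(cgis, fg_sites) if restrict_to_fg_cgis else cgis
    if len(use_cgis) == 0:
        raise ValueError("no CGI contains a foreground site")
    n_fg = _bin_offsets(assign_border_offsets(fg_sites, use_cgis, window),
                        window, bin_width)
    n_bg = _bin_offsets(assign_border_offsets(bg_sites, use_cgis, window),
                        window, bin_width)
    if n_fg.sum() == 0 or n_bg.sum() == 0:
        raise ValueError("no sites fall within the border window")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (n_fg / n_fg.sum()) / (n_bg / n_bg.sum())
    values = np.where(n_bg == 0, np.nan, values)
    return BorderProfile(_bin_edges(window, bin_width), values, n_fg, n_bg,
                         window, bin_width)


def nucleosome_occupancy_profile(fragments: pd.DataFrame, cgis: pd.DataFrame,
                                 window: int = DEFAULT_WINDOW,
                                 bin_width: int = DEFAULT_BIN_WIDTH
                                 ) -> BorderProfile:
    """Mean-normalized fragment-midpoint occupancy around CGI borders.

    Each fragment contributes its midpoint ``floor((start + end) / 2)``;
    per-bin midpoint counts are divided by the mean count over all bins, so
    a flat profile sits at 1.0.
    """
    if len(fragments) == 0:
        raise ValueError("fragment collection is empty")
    mids = pd.DataFrame({
        "chrom": fragments["chrom"],
        "pos": (fragments["start"] + fragments["end"]) // 2,
    })
    counts = _bin_offsets(assign_border_offsets(mids, cgis, window),
                          window, bin_width)
    if counts.sum() == 0:
        raise ValueError("no fragment midpoint within the window of any CGI")
    values = counts / counts.mean()
    return BorderProfile(_bin_edges(window, bin_width), values.astype(float),
                         counts, np.zeros_like(counts), window, bin_width)


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"]))
    return trees


def _membership(sites: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    trees = _trees(intervals)
    return np.fromiter(
        (bool(trees[c][p]) if c in trees else False
         for c, p in zip(sites["chrom"], sites["pos"])),
        dtype=bool, count=len(sites))


def feature_distribution(sites: pd.DataFrame,
                         features: Mapping[str, pd.DataFrame],
                         partition_order: Sequence[str] | None = None
                         ) -> pd.DataFrame:
    """Fraction of sites overlapping each labeled feature set.

    Labels are evaluated independently (a site inside both a gene body and
    a promoter counts toward both) unless ``partition_order`` lists labels
    in priority order, in which case each site is assigned to the first
    matching label and an ``unassigned`` remainder row is added.  Overlap
    uses the half-open convention: a site at an interval's end coordinate
    does not overlap it.
    """
    if len(sites) == 0:
        raise ValueError("empty site set")
    n = len(sites)
    member = {label: _membership(sites, iv) for label, iv in features.items()}
    rows = []
    if partition_order is None:
        for label in features:
            cnt = int(member[label].sum())
            rows.append({"feature": label, "n_sites": cnt, "fraction": cnt / n})
    else:
        assigned = np.zeros(n, dtype=bool)
        for label in partition_order:
            hit = member[label] & ~assigned
            assigned |= member[label]
            cnt = int(hit.sum())
            rows.append({"feature": label, "n_sites": cnt, "fraction": cnt / n})
        cnt = int((~assigned).sum())
        rows.append({"feature": "unassigned", "n_sites": cnt, "fraction": cnt / n})
    return pd.DataFrame(rows)


def overlap_enrichment(fg_sites: pd.DataFrame, intervals: pd.DataFrame,
                       bg_sites: pd.DataFrame) -> tuple[float, float]:
    """Fold enrichment of foreground overlap plus a two-sided exact p-value.

    Fold = (fg overlap fraction) / (bg overlap fraction); the p-value is
    the two-sided hypergeometric (Fisher exact) probability of the observed
    foreground overlap when drawing |fg| sites from the background.
    Requires fg to be a subset of bg and a non-zero background overlap.
    """
    if len(intervals) == 0:
        raise ValueError("interval set is empty")
    _subset_check(fg_sites, bg_sites)
    fg_in = int(_membership(fg_sites, intervals).sum())
    bg_in = int(_membership(bg_sites, intervals).sum())
    n_fg, n_bg = len(fg_sites), len(bg_sites)
    if bg_in == 0:
        raise ValueError("background overlap fraction is zero; fold undefined")
    fold = (fg_in / n_fg) / (bg_in / n_bg)
    table = [[fg_in, n_fg - fg_in], [bg_in - fg_in, (n_bg - n_fg) - (bg_in - fg_in)]]
    _, p = fisher_exact(table, alternative="two-sided")
    return fold, float(p)
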