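"""Replicate merging, depth filtering and per-site methylation-state calls.

A CpG site with merged read counts ``(n_meth, n_unmeth)`` is assigned one
of four population-level states:

``FULL``
    methylated in essentially every cell (methylation level 1),
``HALF``
    methylation level 0.5 — allele-specific methylation in all cells or
    two balanced dominant subclones,
``NONE``
    unmethylated in essentially every cell (level 0),
``DYNAMIC``
    anything else (heterogeneous or changing methylation).

Two decision rules are provided.  The *strict* rule takes the counts
literally: FULL requires zero unmethylated reads, NONE zero methylated
reads, HALF a fraction within ``half_tol`` of 0.5.  At 100x depth with a
~1-2.5% chemistry error this literal rule is dominated by conversion
noise (a truly fully methylated site shows at least one unmethylated read
with probability ~0.95 at e_fn=0.025), so the default *statistical* rule
asks instead whether the minority reads are explainable by the spike-in
calibrated error rates: FULL is accepted when the one-sided exact
binomial tail P(X >= n_unmeth | n, e_fn) >= alpha (and fraction > 0.5),
NONE symmetrically against e_fp, and HALF when the exact two-sided
binomial test of fraction = 0.5 is not rejected.  The rules are evaluated
in the fixed order FULL, NONE, HALF, guaranteeing mutually exclusive
calls; failure of all three yields DYNAMIC.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .spikein import DEFAULT_ERROR_FLOOR, ConversionRates

KEY = ["chrom", "pos", "strand"]
COUNTS = ["n_meth", "n_unmeth"]


class MethClass(str, Enum):
    FULL = "FULL"        # methylation level 1
    HALF = "HALF"        # methylation level 0.5
    NONE = "NONE"        # methylation level 0
    DYNAMIC = "DYNAMIC"  # everything else

    def __str__(self) -> str:  # pragma: no cover
        return self.value


STABLE_CLASSES = (MethClass.FULL.value, MethClass.HALF.value, MethClass.NONE.value)


def merge_replicates(call_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts element-wise over replicates per ``(chrom, pos, strand)``.

    The output key set is the union of the inputs' (a site absent from a
    replicate contributes zero counts); total read depth is conserved.
    """
    if len(call_sets) == 0:
        raise ValueError("need at least one call set")
    merged = (pd.concat(call_sets, ignore_index=True)
              .groupby(KEY, as_index=False)[COUNTS].sum()
              .sort_values(KEY, kind="mergesort")
              .reset_index(drop=True))
    return merged


def merge_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Combine the two strands of each CpG dinucleotide.

    A minus-strand call at position p reports the G-paired cytosine of the
    CpG whose plus-strand C sits at p-1, so every minus call is re-anchored
    to p-1 on "+" and count-summed with a plus call there when present;
    unpaired minus calls pass through at the re-anchored coordinate.
    """
    out = calls.copy()
    minus = out["strand"] == "-"
    out.loc[minus, "pos"] = out.loc[minus, "pos"] - 1
    out["strand"] = "+"
    return (out.groupby(KEY, as_index=False)[COUNTS].sum()
            .sort_values(KEY, kind="mergesort").reset_index(drop=True))


def filter_by_depth(calls: pd.DataFrame, min_depth: int = 100) -> pd.DataFrame:
    """Keep sites with ``n_meth + n_unmeth >= min_depth`` (order-stable)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = calls["n_meth"] + calls["n_unmeth"]
    return calls[depth >= min_depth].reset_index(drop=True)


def half_test_pvalues(n_meth: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p-values against p = 0.5, vectorized.

    For the symmetric p=0.5 null the two-sided p equals twice the smaller
    tail, clipped at 1 (cross-checked against scipy.stats.binomtest).
    """
    k = np.minimum(n_meth, depth - n_meth)
    return np.minimum(1.0, 2.0 * binom.cdf(k, depth, 0.5))


def classify_counts(n_meth, n_unmeth,
                    rates: ConversionRates | None = None,
                    mode: str = "statistical",
                    alpha: float = 0.05,
                    half_tol: float = 0.05,
                    error_floor: float = DEFAULT_ERROR_FLOOR) -> np.ndarray:
    """Vectorized methylation-state calls for arrays of counts.

    Parameters mirror :func:`classify_site`; returns an object array of
    class names.
    """
    m = np.asarray(n_meth, dtype=np.int64)
    u = np.asarray(n_unmeth, dtype=np.int64)
    n = m + u
    if (n < 1).any():
        raise ValueError("every site needs depth >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    frac = m / n

    if mode == "strict":
        # |m/n - 1/2| <= tol in exact integer form: |2m - n| <= 2*tol*n
        near_half = np.abs(2 * m - n) <= 2.0 * half_tol * n + 1e-9
        out = np.where(
            u == 0, MethClass.FULL.value,
            np.where(m == 0, MethClass.NONE.value,
                     np.where(near_half, MethClass.HALF.value,
                              MethClass.DYNAMIC.value)))
        return out.astype(object)
    if mode != "statistical":
        raise ValueError(f"unknown mode {mode!r}")
    if rates is None:
        raise ValueError("statistical mode requires spike-in ConversionRates")

    e_fp, e_fn = rates.floored(error_floor)
    # P(X >= u | n, e_fn): unmethylated reads explainable by inappropriate
    # conversion -> accept FULL.  sf(k-1) is the inclusive upper tail.
    p_full = binom.sf(u - 1, n, e_fn)
    p_none = binom.sf(m - 1, n, e_fp)
    p_half = half_test_pvalues(m, n)

    is_full = (p_full >= alpha) & (frac > 0.5)
    is_none = (p_none >= alpha) & (frac < 0.5) & ~is_full
    is_half = (p_half >= alpha) & ~is_full & ~is_none
    out = np.select(
        [is_full, is_none, is_half],
        [MethClass.FULL.value, MethClass.NONE.value, MethClass.HALF.value],
        default=MethClass.DYNAMIC.value)
    return out.astype(object)


def classify_site(n_meth: int, n_unmeth: int,
                  rates: ConversionRates | None = None,
                  mode: str = "statistical",
                  alpha: float = 0.05,
                  half_tol: float = 0.05,
                  error_floor: float = DEFAULT_ERROR_FLOOR) -> MethClass:
    """Classify a single site; scalar convenience over :func:`classify_counts`."""
    cls = classify_counts(np.array([n_meth]), np.array([n_unmeth]),
                          rates=rates, mode=mode, alpha=alpha,
                          half_tol=half_tol, error_floor=error_floor)
    return MethClass(cls[0])


def classify_sites(calls: pd.DataFrame,
                   rates: ConversionRates | None = None,
                   mode: str = "statistical",
                   alpha: float = 0.05,
                   half_tol: float = 0.05,
                   min_depth: int | None = None,
                   error_floor: float = DEFAULT_ERROR_FLOOR) -> pd.DataFrame:
    """Classify a (merged) call set, optionally applying the depth filter.

    Returns the calls augmented with ``depth``, ``fraction`` and
    ``meth_class`` columns, sorted by coordinate.
    """
    df = calls if min_depth is None else filter_by_depth(calls, min_depth)
    df = df.sort_values(KEY, kind="mergesort").reset_index(drop=True).copy()
    df["depth"] = df["n_meth"] + df["n_unmeth"]
    df["fraction"] = df["n_meth"] / df["depth"]
    df["meth_class"] = classify_counts(
        df["n_meth"].to_numpy(), df["n_unmeth"].to_numpy(),
        rates=rates, mode=mode, alpha=alpha, half_tol=half_tol,
        error_floor=error_floor)
    return df


def downsample_counts(calls: pd.DataFrame, target_mean_depth: float,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binomial thinning of read counts to a target mean depth.

    Each read is retained independently with probability
    ``q = target_mean_depth / current_mean_depth`` (methylated and
    unmethylated counts thinned separately), which leaves the expected
    methylation fraction of every site unchanged.  Reproducible under a
    fixed seed; ``q = 1`` returns the input counts unchanged.
    """
    depth = (calls["n_meth"] + calls["n_unmeth"]).to_numpy()
    if len(calls) == 0:
        return calls.copy()
    current = float(depth.mean())
    if not 0.0 < target_mean_depth <= current * (1 + 1e-12):
        raise ValueError(
            f"target mean depth {target_mean_depth} must be in (0, {current}]")
    q = min(1.0, target_mean_depth / current)
    out = calls.copy()
    if q == 1.0:
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    out["n_meth"] = rng.binomial(calls["n_meth"].to_numpy(), q)
    out["n_unmeth"] = rng.binomial(calls["n_unmeth"].to_numpy(), q)
    return out
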