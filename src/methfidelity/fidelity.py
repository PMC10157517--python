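"""Stable-site intersection between two sampled passages (generations).

A site is *stably maintained* when it receives the same methylation class
(FULL, HALF or NONE) in both generations; DYNAMIC calls never enter a
stable set.  Sites that fail the depth filter in one generation are
absent from that generation's classification and are therefore excluded
from every stable set — coverage dropout is not biological change — while
still counting toward the per-class total of the generation where they do
appear.  The "varied" percentage of a class uses the generation-20 count
as denominator: 100 * (1 - n_stable / n_g20), rounded to the nearest
integer percent for reporting (raw fractions are retained).
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .classify import KEY, STABLE_CLASSES

TABLE_COLUMNS = ["cell_type", "meth_class", "n_g20", "n_g30", "n_stable"]


def _check_cell_type(g20: pd.DataFrame, g30: pd.DataFrame) -> str:
    labels = set()
    for df in (g20, g30):
        if "cell_type" in df.columns and len(df):
            labels |= set(df["cell_type"].unique())
    if len(labels) > 1:
        raise ValueError(f"mixed cell-type labels in fidelity input: {sorted(labels)}")
    return labels.pop() if labels else ""


def stable_intersection(classified_g20: pd.DataFrame,
                        classified_g30: pd.DataFrame,
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Intersect two per-generation classifications.

    Parameters are classified-site tables (``chrom, pos, strand,
    meth_class, depth, fraction, ...``) for the same cell type.

    Returns
    -------
    stable_sets : dict
        Per class in (FULL, HALF, NONE): the sites classified identically
        in both generations, with per-generation depth and fraction.
    table : DataFrame
        One row per class with ``n_g20``, ``n_g30``, ``n_stable`` counts
        (the published-table shape).
    """
    cell_type = _check_cell_type(classified_g20, classified_g30)
    merged = classified_g20.merge(
        classified_g30, on=KEY, suffixes=("_g20", "_g30"))
    same = merged["meth_class_g20"] == merged["meth_class_g30"]

    stable_sets: dict[str, pd.DataFrame] = {}
    rows = []
    keep = [c for c in ("depth_g20", "fraction_g20", "depth_g30", "fraction_g30")
            if c in merged.columns]
    for cls in STABLE_CLASSES:
        stable = merged[same & (merged["meth_class_g20"] == cls)]
        stable = (stable[KEY + keep].assign(meth_class=cls)
                  .sort_values(KEY, kind="mergesort").reset_index(drop=True))
        stable_sets[cls] = stable
        rows.append({
            "cell_type": cell_type,
            "meth_class": cls,
            "n_g20": int((classified_g20["meth_class"] == cls).sum()),
            "n_g30": int((classified_g30["meth_class"] == cls).sum()),
            "n_stable": len(stable),
        })
    return stable_sets, pd.DataFrame(rows, columns=TABLE_COLUMNS)


def fidelity_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Add maintained fractions and integer "varied" percentages.

    ``maintained_fraction = n_stable / n_g20``;
    ``varied_pct = round(100 * (1 - maintained_fraction))`` to the nearest
    integer.  A class with ``n_g20 = 0`` is undefined and reported as
    missing, not as zero.
    """
    out = table.copy()
    maintained, varied = [], []
    for _, row in out.iterrows():
        if row["n_g20"] > 0:
            f = row["n_stable"] / row["n_g20"]
            maintained.append(f)
            varied.append(math.floor(100.0 * (1.0 - f) + 0.5))
        else:
            maintained.append(float("nan"))
            varied.append(pd.NA)
    out["maintained_fraction"] = maintained
    out["varied_pct"] = pd.array(varied, dtype="Int64")
    return out


def fidelity_table_from_counts(
        counts: Mapping[str, Mapping[str, tuple[int, int, int]]]) -> pd.DataFrame:
    """Build a fidelity table from printed per-class counts.

    ``counts[cell_type][meth_class] = (n_g20, n_g30, n_stable)``.
    """
    rows = []
    for cell_type, per_class in counts.items():
        for cls in STABLE_CLASSES:
            if cls not in per_class:
                continue
            g20, g30, stable = per_class[cls]
            if not (0 <= stable <= min(g20, g30)):
                raise ValueError(
                    f"{cell_type}/{cls}: n_stable {stable} exceeds min(n_g20, n_g30)")
            rows.append({"cell_type": cell_type, "meth_class": cls,
                         "n_g20": g20, "n_g30": g30, "n_stable": stable})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
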