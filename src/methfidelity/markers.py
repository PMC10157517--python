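"""Cell-type-specific stably maintained fully methylated CpG sites.

A marker for cell type T is a site stably FULL in T and stably NONE in
every other cell type.  Stability (same class at both generations) and
depth-passing coverage in all cell types are enforced by construction:
membership in a stable set requires classification, hence coverage, at
both generations of that cell type.  Marker sets of different cell types
are pairwise disjoint by definition (a site cannot be both FULL and NONE
in the same cell type).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .classify import KEY

SiteKey = tuple  # (chrom, pos, strand)


def _as_keyset(sites) -> frozenset:
    if isinstance(sites, pd.DataFrame):
        if len(sites) == 0:
            return frozenset()
        return frozenset(map(tuple, sites[KEY].itertuples(index=False)))
    return frozenset(tuple(s) for s in sites)


def find_markers(stable_sets_by_cell_type: Mapping[str, Mapping[str, object]]
                 ) -> pd.DataFrame:
    """Identify marker sites across >=2 cell types.

    Parameters
    ----------
    stable_sets_by_cell_type
        ``{cell_type: {"FULL": sites, "NONE": sites}}`` where ``sites`` is a
        DataFrame with chrom/pos/strand columns or an iterable of
        ``(chrom, pos, strand)`` tuples (stable sets from the fidelity stage).

    Returns
    -------
    DataFrame with columns ``chrom, pos, strand, marker_for,
    classes_elsewhere``, coordinate-sorted within each cell type group.
    """
    cell_types = list(stable_sets_by_cell_type)
    if len(cell_types) < 2:
        raise ValueError("marker discovery requires at least 2 cell types")
    full = {t: _as_keyset(stable_sets_by_cell_type[t].get("FULL", ()))
            for t in cell_types}
    none = {t: _as_keyset(stable_sets_by_cell_type[t].get("NONE", ()))
            for t in cell_types}

    rows = []
    for t in cell_types:
        markers = full[t]
        others = [o for o in cell_types if o != t]
        for o in others:
            markers = markers & none[o]
        elsewhere = ";".join(f"{o}=NONE" for o in others)
        for chrom, pos, strand in sorted(markers):
            rows.append((chrom, pos, strand, t, elsewhere))
    out = pd.DataFrame(rows, columns=KEY + ["marker_for", "classes_elsewhere"])
    return out.sort_values(["marker_for"] + KEY, kind="mergesort").reset_index(drop=True)
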