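"""Published per-class CpG site counts for three human cell lines.

Reference counts from ultra-deep (>=100x merged) RRBS temporal profiling
of ARPE-19 (retinal pigment epithelium), Jurkat (T lymphocyte) and SW1353
(chondrosarcoma) cells sampled at culture generations 20 and 30: for each
methylation-level class (FULL = level 1, HALF = 0.5, NONE = 0) the number
of sites assigned that class at generation 20, at generation 30, and at
both (the stable intersection).  These printed counts serve as a desk-scale
input for the fidelity summary; the raw sequencing data behind them are
not required.
"""

from __future__ import annotations

import pandas as pd

from .fidelity import fidelity_summary, fidelity_table_from_counts

#: counts[cell_type][meth_class] = (n_g20, n_g30, n_stable)
REFERENCE_FIDELITY_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "ARPE-19": {
        "FULL": (313457, 150010, 122868),
        "HALF": (41922, 41942, 41705),
        "NONE": (231851, 232886, 196276),
    },
    "Jurkat": {
        "FULL": (144948, 76749, 49137),
        "HALF": (46482, 46565, 46123),
        "NONE": (192046, 196297, 166546),
    },
    "SW1353": {
        "FULL": (35511, 34554, 18813),
        "HALF": (33009, 33047, 32499),
        "NONE": (270669, 322316, 230500),
    },
}


def reference_fidelity_table(with_summary: bool = True) -> pd.DataFrame:
    """The reference counts as a fidelity table, optionally summarized."""
    table = fidelity_table_from_counts(REFERENCE_FIDELITY_COUNTS)
    return fidelity_summary(table) if with_summary else table
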