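"""Bisulfite chemistry error rates estimated from spike-in controls.

Two synthetic control sequences of known methylation status are carried
through library preparation: a fully *unmethylated* spike-in, whose
cytosines should all convert (reads reporting C there are false
methylation), and a fully *methylated* spike-in, whose cytosines should
all resist conversion (reads reporting T there are inappropriate
conversion, i.e. false demethylation).  Pooling all cytosines of each
control gives one global pair of rates per sample group, which the
error-aware site classifier uses as its binomial null probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: floor applied to either error rate before use in binomial tests; a zero
#: estimated error at finite depth is a sampling artifact and would make
#: the null degenerate.
DEFAULT_ERROR_FLOOR = 1e-6


@dataclass(frozen=True)
class ConversionRates:
    """Spike-in-derived bisulfite error rates.

    Attributes
    ----------
    conversion_rate
        Fraction of truly unmethylated cytosines read as converted;
        its complement is the false-methylation rate ``e_fp``.
    inappropriate_conversion_rate
        Fraction of truly methylated cytosines read as converted; this is
        the false-demethylation rate ``e_fn`` directly.
    n_unmeth_spike_obs, n_meth_spike_obs
        Total cytosine observations backing each rate.
    """

    conversion_rate: float
    inappropriate_conversion_rate: float
    n_unmeth_spike_obs: int = 0
    n_meth_spike_obs: int = 0

    def __post_init__(self):
        for r in (self.conversion_rate, self.inappropriate_conversion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")

    @property
    def false_methylation_rate(self) -> float:
        """e_fp: probability a truly unmethylated C reads methylated."""
        return 1.0 - self.conversion_rate

    @property
    def false_demethylation_rate(self) -> float:
        """e_fn: probability a truly methylated C reads unmethylated."""
        return self.inappropriate_conversion_rate

    def floored(self, floor: float = DEFAULT_ERROR_FLOOR) -> tuple[float, float]:
        """(e_fp, e_fn) with the configured numerical floor applied."""
        return (max(self.false_methylation_rate, floor),
                max(self.false_demethylation_rate, floor))

    @classmethod
    def from_error_rates(cls, e_fp: float, e_fn: float,
                         n_unmeth_spike_obs: int = 0,
                         n_meth_spike_obs: int = 0) -> "ConversionRates":
        return cls(1.0 - e_fp, e_fn, n_unmeth_spike_obs, n_meth_spike_obs)


def estimate_conversion_rates(unmeth_spike_calls: pd.DataFrame,
                              meth_spike_calls: pd.DataFrame) -> ConversionRates:
    """Estimate both error rates by pooling all spike-in cytosines.

    ``conversion_rate`` is the converted (unmethylated-read) fraction on the
    unmethylated control; ``inappropriate_conversion_rate`` is the converted
    fraction on the methylated control.  Either control with zero total
    depth leaves its rate undefined and raises ``ValueError``.
    """
    u_conv = int(unmeth_spike_calls["n_unmeth"].sum())
    u_tot = u_conv + int(unmeth_spike_calls["n_meth"].sum())
    m_conv = int(meth_spike_calls["n_unmeth"].sum())
    m_tot = m_conv + int(meth_spike_calls["n_meth"].sum())
    if u_tot == 0:
        raise ValueError("unmethylated spike-in has zero total depth; "
                         "conversion rate undefined")
    if m_tot == 0:
        raise ValueError("methylated spike-in has zero total depth; "
                         "inappropriate conversion rate undefined")
    return ConversionRates(u_conv / u_tot, m_conv / m_tot, u_tot, m_tot)


def split_spike_calls(calls: pd.DataFrame,
                      unmeth_prefix: str = "spike_unmeth",
                      meth_prefix: str = "spike_meth"):
    """Split a combined call set into (unmeth spike, meth spike, genomic)
    by contig-name prefix."""
    chrom = calls["chrom"].astype(str)
    is_u = chrom.str.startswith(unmeth_prefix)
    is_m = chrom.str.startswith(meth_prefix) & ~is_u
    rest = ~(is_u | is_m)
    return (calls[is_u].reset_index(drop=True),
            calls[is_m].reset_index(drop=True),
            calls[rest].reset_index(drop=True))
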