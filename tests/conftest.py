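import math
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def calls_df(rows):
    """rows: iterable of (chrom, pos, strand, n_meth, n_unmeth)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth"])


def intervals_df(rows):
    """rows: iterable of (chrom, start, end[, name])."""
    rows = [r if len(r) == 4 else (*r, "") for r in rows]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Independent exact-binomial oracles, built on math.comb rather than scipy,
# used to freeze expected classification outcomes.

@lru_cache(maxsize=None)
def binom_pmf(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def upper_tail(k, n, p):
    """P(X >= k) by direct pmf summation."""
    return sum(binom_pmf(i, n, p) for i in range(max(k, 0), n + 1))


def two_sided_half_p(m, n):
    """Exact two-sided binomial p-value against p=0.5 (pmf summation:
    probabilities of all outcomes no more likely than the observed one)."""
    obs = binom_pmf(m, n, 0.5)
    return min(1.0, sum(binom_pmf(i, n, 0.5) for i in range(n + 1)
                        if binom_pmf(i, n, 0.5) <= obs * (1 + 1e-12)))


def oracle_classify(n_meth, n_unmeth, e_fp, e_fn, alpha=0.05):
    """Scalar reference implementation of the statistical decision rule."""
    n = n_meth + n_unmeth
    frac = n_meth / n
    if upper_tail(n_unmeth, n, e_fn) >= alpha and frac > 0.5:
        return "FULL"
    if upper_tail(n_meth, n, e_fp) >= alpha and frac < 0.5:
        return "NONE"
    if two_sided_half_p(n_meth, n) >= alpha:
        return "HALF"
    return "DYNAMIC"


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic study shared by read-only tests."""
    from methfidelity import SimulationConfig, simulate_dataset
    return simulate_dataset(SimulationConfig(n_sites=3000, seed=11))
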