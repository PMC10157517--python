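"""Synthetic RRBS study generator with known ground truth.

Emulates the study design end to end: three cell types sampled at culture
generations 20 and 30 in triplicate, per-CpG read counts at a merged
depth of roughly 120x, spike-in controls carrying the same bisulfite
error process, CpG-island and gene annotations, and MNase fragments
enriched at island borders.  Every site carries a true population state
(FULL / HALF / NONE / DYNAMIC, with a true methylated fraction theta of
1, 0.5, 0, or a draw from a bimodal Beta mixture kept away from 0, 0.5
and 1 so classes stay identifiable at ~100x depth).  Reads report
methylation with probability ``theta*(1-e_fn) + (1-theta)*e_fp``.

Planted structure:

* ``marker_count`` sites per cell type are true markers (FULL in that
  cell type, NONE in the others) and are exempt from state flips;
* a fraction of FULL-in-all-cell-types sites is placed within the first
  ``border_breadth`` bp inside CGI borders;
* every other site's generation-30 state changes with probability
  ``flip_prob`` to a different class (drawn from the remaining classes'
  renormalized proportions), so the expected maintained fraction of a
  class is exactly ``1 - flip_prob`` at truth level.

Coverage: each site has a locus-specific propensity G ~ Gamma(shape
``depth_shape``, mean 1) shared across replicates, generations and cell
types (RRBS coverage is driven by local fragment structure), and each
replicate draws depth ~ Poisson(mean_depth * G).

Everything is reproducible from a single integer seed; the same config
and seed produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio

STATES = ("FULL", "HALF", "NONE", "DYNAMIC")
STATE_THETA = {"FULL": 1.0, "HALF": 0.5, "NONE": 0.0}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator (defaults are the study design)."""

    n_sites: int = 10_000
    cell_types: tuple[str, ...] = ("typeA", "typeB", "typeC")
    generations: tuple[int, int] = (20, 30)
    n_replicates: int = 3
    mean_depth: float = 40.0          # per replicate; merged ~ 120x
    depth_shape: float = 25.0         # gamma shape of the coverage propensity
    state_proportions: dict = field(default_factory=lambda: {
        "FULL": 0.20, "HALF": 0.05, "NONE": 0.30, "DYNAMIC": 0.45})
    e_fp: float = 0.01                # false methylation (1 - conversion rate)
    e_fn: float = 0.025               # inappropriate conversion
    flip_prob: float = 0.3            # per-site inter-generation state change
    marker_count: int = 50            # planted markers per cell type
    n_cgis: int = 50
    cgi_length: int = 1200
    cgi_spacing: int = 8000
    border_breadth: int = 150         # planted border-FULL placement breadth
    border_full_frac: float = 0.25    # share of FULL mass planted at borders
    n_spike_sites: int = 200
    read_sampling: str = "binomial"   # "binomial" | "expected"
    seed: int = 0

    def __post_init__(self):
        props = self.state_proportions
        if set(props) != set(STATES):
            raise ValueError(f"state_proportions must cover {STATES}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("state_proportions must sum to 1")
        for p in (*props.values(), self.e_fp, self.e_fn, self.flip_prob,
                  self.border_full_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.read_sampling not in ("binomial", "expected"):
            raise ValueError("read_sampling must be 'binomial' or 'expected'")
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("n_sites and n_replicates must be >= 1")

    @property
    def chrom_length(self) -> int:
        return (self.n_cgis + 1) * self.cgi_spacing


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`."""

    config: SimulationConfig
    calls: dict            # (cell_type, generation, replicate) -> calls DataFrame
    spikes: dict           # (cell_type, generation) -> (unmeth df, meth df)
    cgis: pd.DataFrame
    features: dict         # label -> intervals DataFrame
    truth: pd.DataFrame    # per site x cell type ground truth

    def merged_calls(self, cell_type: str, generation: int) -> pd.DataFrame:
        from .classify import merge_replicates
        reps = [self.calls[(cell_type, generation, r)]
                for r in range(self.config.n_replicates)]
        return merge_replicates(reps)


def _draw_dynamic_theta(rng: np.random.Generator, size: int) -> np.ndarray:
    """Bimodal Beta mixture on (0.05, 0.95) excluding (0.40, 0.60)."""
    out = np.empty(size)
    todo = np.arange(size)
    while len(todo):
        comp = rng.random(len(todo)) < 0.5
        draw = np.where(comp, rng.beta(15, 45, len(todo)),
                        rng.beta(45, 15, len(todo)))
        ok = (draw > 0.05) & (draw < 0.95) & ~((draw > 0.40) & (draw < 0.60))
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _flip_states(rng: np.random.Generator, states: np.ndarray,
                 proportions: Mapping[str, float], flip_prob: float,
                 exempt: np.ndarray) -> np.ndarray:
    """Redraw flipped sites' states from the *other* classes' proportions."""
    out = states.copy()
    flip = (rng.random(len(states)) < flip_prob) & ~exempt
    for cur in STATES:
        sel = flip & (states == cur)
        if not sel.any():
            continue
        others = [s for s in STATES if s != cur]
        probs = np.array([proportions[s] for s in others], dtype=float)
        probs /= probs.sum()
        out[sel] = rng.choice(others, size=int(sel.sum()), p=probs)
    return out


def _counts(rng: np.random.Generator, depth: np.ndarray, p_obs: np.ndarray,
            sampling: str) -> np.ndarray:
    if sampling == "binomial":
        return rng.binomial(depth, p_obs)
    return np.floor(depth * p_obs + 0.5).astype(np.int64)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic study (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"

    # --- annotations -----------------------------------------------------
    pad = (cfg.cgi_spacing - cfg.cgi_length) // 2
    cgi_starts = np.arange(cfg.n_cgis) * cfg.cgi_spacing + pad
    cgis = pd.DataFrame({
        "chrom": chrom,
        "start": cgi_starts,
        "end": cgi_starts + cfg.cgi_length,
        "name": [f"CGI_{i + 1}" for i in range(cfg.n_cgis)],
    })
    gene_starts = np.arange(500, cfg.chrom_length - 3500, 7000)
    features = {
        "gene_body": pd.DataFrame({
            "chrom": chrom, "start": gene_starts, "end": gene_starts + 3000,
            "name": [f"gene_{i + 1}" for i in range(len(gene_starts))]}),
        "promoter": pd.DataFrame({
            "chrom": chrom,
            "start": np.maximum(gene_starts - 500, 0), "end": gene_starts,
            "name": [f"promoter_{i + 1}" for i in range(len(gene_starts))]}),
    }

    # --- site placement --------------------------------------------------
    p_full = cfg.state_proportions["FULL"]
    n_border = min(int(round(cfg.border_full_frac * p_full * cfg.n_sites)),
                   cfg.n_sites)
    cgi_idx = rng.integers(0, cfg.n_cgis, n_border)
    right = rng.random(n_border) < 0.5
    off = rng.integers(0, cfg.border_breadth, n_border)  # inside offsets 0..b-1
    border_pos = np.where(
        right,
        cgis["end"].to_numpy()[cgi_idx] - 1 - off,
        cgis["start"].to_numpy()[cgi_idx] + off)
    border_pos = np.unique(border_pos)
    n_border = len(border_pos)

    n_rest = cfg.n_sites - n_border
    candidates = rng.choice(cfg.chrom_length, size=min(cfg.chrom_length,
                                                       2 * cfg.n_sites + 1000),
                            replace=False)
    candidates = candidates[~np.isin(candidates, border_pos)][:n_rest]
    if len(candidates) < n_rest:
        raise ValueError("chromosome too short for the requested site count")
    positions = np.sort(np.concatenate([border_pos, candidates]))
    is_border = np.isin(positions, border_pos)

    # --- true states -----------------------------------------------------
    n, types = cfg.n_sites, list(cfg.cell_types)
    non_border_idx = np.flatnonzero(~is_border)
    perm = rng.permutation(non_border_idx)
    marker_of = np.full(n, "", dtype=object)
    need = cfg.marker_count * len(types)
    if need > len(perm):
        raise ValueError("not enough non-border sites to plant markers")
    for i, t in enumerate(types):
        marker_of[perm[i * cfg.marker_count:(i + 1) * cfg.marker_count]] = t

    state_names = np.array(STATES, dtype=object)
    probs = np.array([cfg.state_proportions[s] for s in STATES])
    g20_states: dict[str, np.ndarray] = {}
    g30_states: dict[str, np.ndarray] = {}
    for t in types:
        st = rng.choice(state_names, size=n, p=probs)
        st[is_border] = "FULL"
        st[marker_of == t] = "FULL"
        st[(marker_of != "") & (marker_of != t)] = "NONE"
        g20_states[t] = st
        g30_states[t] = _flip_states(rng, st, cfg.state_proportions,
                                     cfg.flip_prob, exempt=(marker_of != ""))

    def _theta(states: np.ndarray) -> np.ndarray:
        th = np.empty(n)
        for s, v in STATE_THETA.items():
            th[states == s] = v
        dyn = states == "DYNAMIC"
        th[dyn] = _draw_dynamic_theta(rng, int(dyn.sum()))
        return th

    g20_theta = {t: _theta(g20_states[t]) for t in types}
    g30_theta: dict[str, np.ndarray] = {}
    for t in types:
        th = g20_theta[t].copy()
        changed = g30_states[t] != g20_states[t]
        th[changed] = _theta(g30_states[t])[changed]
        g30_theta[t] = th

    # --- read counts -----------------------------------------------------
    propensity = rng.gamma(cfg.depth_shape, 1.0 / cfg.depth_shape, n)
    calls: dict = {}
    gen20, gen30 = cfg.generations
    for t in types:
        for gen, theta in ((gen20, g20_theta[t]), (gen30, g30_theta[t])):
            p_obs = theta * (1 - cfg.e_fn) + (1 - theta) * cfg.e_fp
            for r in range(cfg.n_replicates):
                depth = rng.poisson(cfg.mean_depth * propensity)
                n_meth = _counts(rng, depth, p_obs, cfg.read_sampling)
                covered = depth > 0
                calls[(t, gen, r)] = pd.DataFrame({
                    "chrom": chrom,
                    "pos": positions[covered],
                    "strand": "+",
                    "n_meth": n_meth[covered],
                    "n_unmeth": (depth - n_meth)[covered],
                })

    # --- spike-ins (merged over replicates, one pair per sample group) ---
    spikes: dict = {}
    spike_pos = np.arange(cfg.n_spike_sites) * 5 + 10
    merged_mean = cfg.mean_depth * cfg.n_replicates
    for t in types:
        for gen in cfg.generations:
            sp = {}
            for contig, p_obs in (("spike_unmeth_1", cfg.e_fp),
                                  ("spike_meth_1", 1.0 - cfg.e_fn)):
                depth = rng.poisson(merged_mean, cfg.n_spike_sites)
                depth = np.maximum(depth, 1)
                n_meth = _counts(rng, depth, np.full(cfg.n_spike_sites, p_obs),
                                 cfg.read_sampling)
                sp[contig] = pd.DataFrame({
                    "chrom": contig, "pos": spike_pos, "strand": "+",
                    "n_meth": n_meth, "n_unmeth": depth - n_meth,
                })
            spikes[(t, gen)] = (sp["spike_unmeth_1"], sp["spike_meth_1"])

    # --- truth table ------------------------------------------------------
    truth_rows = []
    for t in types:
        truth_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": positions, "strand": "+", "cell_type": t,
            "state_g20": g20_states[t], "theta_g20": g20_theta[t],
            "state_g30": g30_states[t], "theta_g30": g30_theta[t],
            "marker_for": marker_of, "border_planted": is_border,
        }))
    truth = pd.concat(truth_rows, ignore_index=True)

    return SimulatedDataset(cfg, calls, spikes, cgis, features, truth)


def simulate_mnase_fragments(cgis: pd.DataFrame, n_fragments: int,
                             border_enrichment_fold: float = 5.0,
                             fragment_length: int = 150,
                             border_breadth: int = 150,
                             span: int | None = None,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None
                             ) -> pd.DataFrame:
    """Nucleosome-protected fragments with border-enriched midpoints.

    Midpoints mix a uniform background over the chromosome span with a
    component confined to the first ``border_breadth`` bp inside each CGI
    border, weighted so the midpoint density there is
    ``border_enrichment_fold`` times the background density.
    """
    if len(cgis) == 0:
        raise ValueError("CGI set is empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_fragments == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=object),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    chrom = cgis["chrom"].iloc[0]
    L = int(span if span is not None else cgis["end"].max() + 2000)
    breadth = np.minimum(border_breadth,
                         (cgis["end"] - cgis["start"]).to_numpy() // 2)
    area = int((2 * breadth).sum())
    fold = float(border_enrichment_fold)
    ratio = (fold - 1.0) * area / L
    p_enriched = max(0.0, ratio / (1.0 + ratio))

    from_border = rng.random(n_fragments) < p_enriched
    mids = rng.integers(0, L, n_fragments)
    k = int(from_border.sum())
    if k:
        ci = rng.integers(0, len(cgis), k)
        right = rng.random(k) < 0.5
        off = rng.integers(0, np.maximum(breadth[ci], 1))
        starts = cgis["start"].to_numpy()[ci]
        ends = cgis["end"].to_numpy()[ci]
        mids[from_border] = np.where(right, ends - 1 - off, starts + off)

    start = np.maximum(mids - fragment_length // 2, 0)
    return pd.DataFrame({"chrom": chrom, "start": start,
                         "end": start + fragment_length})


def write_dataset(dataset: SimulatedDataset, outdir) -> Path:
    """Write every generated input in the formats the readers accept."""
    out = Path(outdir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    (out / "spikes").mkdir(exist_ok=True)
    cfg = dataset.config
    for (t, gen, r), df in sorted(dataset.calls.items()):
        mio.write_methylation_calls(df, out / "calls" / f"{t}_g{gen}_rep{r + 1}.cov")
    for (t, gen), (unmeth, meth) in sorted(dataset.spikes.items()):
        mio.write_methylation_calls(unmeth, out / "spikes" / f"{t}_g{gen}_spike_unmeth.cov")
        mio.write_methylation_calls(meth, out / "spikes" / f"{t}_g{gen}_spike_meth.cov")
    mio.write_intervals(dataset.cgis, out / "cgi.bed")
    for label, iv in dataset.features.items():
        mio.write_intervals(iv, out / f"features_{label}.bed")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                         float_format="%.10g")
    return out
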