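# Methods

## The problem and the model

Bulk bisulfite data report, per CpG site, counts `(n_meth, n_unmeth)` of
reads carrying an unconverted (methylated) or converted (unmethylated)
cytosine. The population methylation level is `ML = n_meth / n`. Sites
with ML = 1 or ML = 0 are homogeneous across the sampled cells; ML = 0.5
is compatible with allele-specific methylation in every cell or with two
balanced subclones. Because bisulfite chemistry is imperfect, observed
counts are a noisy readout of the true methylated fraction θ:

    P(read reports methylated) = θ·(1 − e_fn) + (1 − θ)·e_fp

where `e_fp` (false methylation) is the complement of the conversion
rate measured on an unmethylated spike-in, and `e_fn` (false
demethylation, "inappropriate conversion") is measured directly on a
methylated spike-in. Both rates are pooled over all spike-in cytosines
of a sample group — single global rates per library, matching how such
controls are normally reported — and floored at 1e−6 before use so that
a sampling-zero estimate cannot produce a degenerate binomial null.

## Site classification

At the working depth (≥ 100× after merging triplicates) a truly fully
methylated site still shows ≥ 1 unmethylated read with probability
≈ 95% when `e_fn` = 0.025, so a literal zero-minority-read rule mostly
measures chemistry, not biology. The default *statistical* rule
therefore asks whether the minority reads are explainable by the
calibrated error process, evaluated in a fixed order that makes the
classes mutually exclusive:

1. **FULL** if `P(X ≥ n_unmeth | n, e_fn) ≥ α` (one-sided exact binomial
   tail) and fraction > 0.5;
2. **NONE** if `P(X ≥ n_meth | n, e_fp) ≥ α` and fraction < 0.5;
3. **HALF** if the exact two-sided binomial test of fraction = 0.5 has
   p ≥ α (for the symmetric null this is twice the smaller tail,
   clipped at 1; verified against `scipy.stats.binomtest`);
4. **DYNAMIC** otherwise.

Defaults: α = 0.05, min_depth = 100. These are accept-the-null
decisions, so no multiple-testing correction applies (BH-style control
is undefined for acceptances); α is exposed in the configuration. The
*strict* mode (FULL ⇔ `n_unmeth` = 0, NONE ⇔ `n_meth` = 0, HALF ⇔
|fraction − ½| ≤ `half_tol`, default 0.05, computed in exact integer
arithmetic) is retained for the zero-noise limit and for sensitivity
analyses. Per-site classification probabilities of the statistical rule
are step functions of depth: at n = 120 the FULL call tolerates up to 6
unmethylated reads (tail at 7 drops to 0.032 < α) and the NONE call up
to 3 methylated reads.

Strand handling: Bismark coverage files often omit strand, so "+" is
assumed; an opt-in `merge_strands` operation re-anchors minus-strand
calls to the plus-strand C of the CpG (position − 1) and sums counts.
Whether to merge strands is left to the user, as published analyses vary.
The ≥ 100× filter is applied per generation independently; a site
passing in only one generation contributes to that generation's class
totals but can never be "stable" — coverage dropout is not treated as
biological change.

## Temporal fidelity, markers

Stable sets are exact class-wise intersections of the two generations'
classifications. The "varied" percentage of a class uses the
generation-20 count as denominator, `100·(1 − n_stable/n_G20)`, rounded
half-up to integer percent (raw fractions are always retained); this is
the convention under which the packaged reference counts for ARPE-19,
Jurkat and SW1353 reproduce their printed 61/66/47% FULL-class values.
A marker for cell type T is a site stably FULL in T and stably NONE in
every other profiled cell type, which automatically requires
depth-passing coverage in all cell types at both generations (no
imputation: absence of evidence is not NONE). Marker sets are pairwise
disjoint by construction.

## Border metaplots

Each site (or MNase fragment midpoint) is assigned to the nearest CGI
border within ±window (default 1500 bp, bins of 50 bp; a 150 bp feature
spans ≥ 3 bins). For one island with borders at `start` and `end − 1`
the offset is the distance to the nearer border, positive inside
`[start, end)`; across islands the assignment minimizes
(|distance|, border coordinate, left-before-right), a total order that
makes ties deterministic and lets a brute-force scan serve as oracle.
Islands shorter than twice the window simply fold at their midpoint.
Enrichment is background-normalized — per-bin foreground share over
background share, with all depth-passing sites as background — because
RRBS coverage is itself strongly concentrated near islands; raw counts
would reproduce assay bias rather than enrichment. Bins with zero
background are reported as undefined (NaN), never as zero. By default
only islands containing ≥ 1 foreground site are profiled. Occupancy
profiles use fragment midpoints (standard MNase practice) divided by the
mean bin count, so a flat profile sits at 1. The offset exactly at
+window folds into the outermost bin.

Feature distributions count a site toward every label it overlaps
(half-open intervals) unless a priority partition is requested, in which
case an explicit `unassigned` remainder is reported. The generic overlap
test is a two-sided Fisher/hypergeometric comparison of foreground
overlap against the background it was drawn from.

## The synthetic study

The generator emulates the study design rather than any particular
genome: one chromosome, 50 CGIs of 1.2 kb spaced 8 kb apart, a simple
gene-body/promoter annotation, three cell types × two generations ×
three replicates. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `mean_depth` | 40×/replicate | merged triplicates ≈ 120×, the ultra-deep regime the ≥100× filter presumes |
| `depth_shape` | 25 | per-site coverage propensity G ~ Gamma(25, mean 1), shared across all samples of a site (RRBS depth is locus-driven); CV 0.2 keeps most sites above the filter while producing realistic dropout |
| `e_fp`, `e_fn` | 0.01, 0.025 | a 99% conversion rate and 2.5% inappropriate conversion, the error regime typical of commercial bisulfite kits |
| `state_proportions` | 0.20/0.05/0.30/0.45 | qualitative class mix of deep RRBS call sets: NONE and DYNAMIC dominate, HALF is rare |
| `flip_prob` | 0.3 | inter-generation true-state change, in the range implied by observed FULL-class variation; a flipped site re-draws its class from the *other* classes' renormalized proportions, so the truth-level maintained fraction of every class is exactly 1 − flip_prob |
| `marker_count` | 50/cell type | planted markers (flip-exempt, i.e. genuinely stable) |
| `border_full_frac` | 0.25 | share of the FULL mass placed uniformly within the first 150 bp inside island borders, in all cell types — these all-FULL sites double as negative controls for marker specificity |
| DYNAMIC θ | ½·Beta(15,45) + ½·Beta(45,15), truncated to (0.05, 0.95) \ (0.40, 0.60) | keeps heterogeneous sites identifiable at ~120×; no model for them is established, identifiability is the design goal |

Read sampling is binomial by default. `read_sampling="expected"` sets
`n_meth = round(θ·depth)` and exists to realize the zero-noise limit:
with both error rates at zero the only remaining stochasticity is
allele/cell sampling of reads, which alone scatters a true-HALF site
outside the strict tolerance ~24% of the time at 120×, so "exact truth
recovery" is a meaningful contract only with all noise sources off.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: genomic sequence context (no MspI
digest, no CpG clustering beyond the planted island geometry), M-bias
and position-dependent error, overdispersed (beta-binomial) methylation
counts from subclonal structure, correlated methylation of neighboring
sites, and per-class differences in temporal stability (one `flip_prob`
serves all classes; real unmethylated sites are more stable than
methylated ones).

## Numerical and degenerate-input choices

All tail probabilities come from `scipy.stats.binom`; the vectorized
half-test is cross-checked against `scipy.stats.binomtest` in the test
suite, and classification decisions are checked against an independent
`math.comb` pmf-summation implementation. Coordinates are 0-based
half-open internally; only the Bismark reader shifts (1-based → 0-based),
and the percentage column is never trusted (counts win, with a warning
on disagreement). Empty site tables write header-only files and read
back as empty frames. Zero-depth spike-in controls, empty
foregrounds/backgrounds, windows not divisible by the bin width, and
`min_depth < 1` are errors, not silent defaults. Binomial thinning
(`downsample_counts`) thins both counts with the same retention
probability, leaving every site's expected methylation fraction
unchanged; a target above the current mean depth is an error.

## Known limitations

* Marker discovery requires a site to survive six independent
  accept-the-null screens (FULL at two generations in one cell type,
  NONE at two generations in two others) plus the ≥100× filter in six
  merged samples; at α = 0.05 and 120× the per-screen acceptance is
  ≈ 0.97, so even genuinely planted markers are recovered at roughly
  50–60% under the default conditions. Raising depth or α, or relaxing
  the all-cell-types coverage requirement, trades specificity for yield.
* The HALF class conflates allelic methylation with balanced subclones;
  distinguishing them needs phased or single-cell data.
* Fidelity is defined over two time points; no per-site transition
  process is estimated.
* Profiles are descriptive: no statistical test of profile shape is
  performed.
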