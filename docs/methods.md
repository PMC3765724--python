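# Methods

## The measurement model

The pipeline analyses polysome profiling read out per gradient fraction.
mRNA–ribosome complexes are separated on a sucrose gradient and pooled into
fractions S1..Sk: S1 collects free mRNA and mRNA carrying an incomplete
ribosome, S2 the monosome, S3..Sk polysomes of increasing size. Each
fraction, plus an unfractionated reference aliquot (S0), is hybridised to an
array carrying every gene in duplicate alongside empty control spots. The
same RNA mass (5 µg) is loaded per array regardless of how much RNA the
fraction contained, so raw intensities measure *within-fraction* mRNA shares
and must be corrected back to the fraction's total RNA quantity before
per-gene proportions across fractions mean anything.

Per condition, five independent cultures give five replicate series of
arrays. The default geometry is five fractions under stress and seven under
optimal growth, with fraction → mean-ribosome calibrations
(0, 1, 2.1, 3.9, 8.4) and (0, 1, 2, 4, 7, 10, 14) respectively. The stress
calibration is the measured one; the optimal-growth map is a placeholder
constrained by the known anchors (monosome = 1; heaviest fraction averaging
14 ribosomes, maximum 18) and is deliberately config-supplied —
substitute a measured calibration when you have one.

## Normalization

Chain: per-spot background subtraction (clipped at 0, so proportions stay
non-negative) → duplicate averaging → expression cutoff → total-RNA
correction → per-gene proportioning. The cutoff of each array is the mean of
its background-corrected empty spots plus one sample SD; a gene is kept for
a series if it exceeds the cutoff on at least one of the series' arrays
(union semantics, S0 included). The correction multiplies each gene value by
`rna_total_f / loaded_mass`, after which the row-normalised values equal the
gene's loading distribution exactly in the zero-noise limit — this exactness
is tested as an oracle (simulate → normalize round trip to 1e-9).

A per-array equal-total rescaling (`equalize_arrays=True`) is available for
data with array-to-array gain drift but is **off** by default: rescaling to
equal total signal replaces the array's denominator (total RNA composition)
by mRNA-only composition and is incompatible with the subsequent total-RNA
correction — algebraically the corrected value becomes A·T²/mRNA instead of
A — so it would silently distort cross-fraction proportions whenever rRNA
content varies across fractions (it always does). With simulated arrays the
gain is constant and the rescaling is unnecessary; with real data, gain
correction should use spike-ins or be folded into the rna_total estimate.

Genes are summarized only with ≥ 3 complete series (of 5); missing-fraction
genes are dropped per series.

## Translatome estimation

Occupancy per series is Σ proportions over S2..Sk (equivalently 1 − S1);
the per-gene value is the arithmetic mean over series. The peak fraction is
called by a bootstrap on residuals: per-gene residuals of each series from
the across-series mean profile (translated fractions only) are resampled
with replacement *within fraction, across series* — preserving
fraction-specific variance with only five series — added back to the mean,
clipped at 0, and the argmax recorded. Default 10 000 iterations (the
pipeline's fast profile uses 1000; calls are stable between the two on
synthetic data) at 95% confidence. If no single fraction reaches the
confidence level, the call widens: the most frequent fraction annexes its
higher-frequency adjacent neighbour (ties towards the heavier fraction)
until the set's cumulative frequency reaches the threshold. Whether the
original procedure also resampled across fractions is not determinable; the
within-fraction choice is the declared default.

Density is defined only for single-fraction peaks (widened calls are
excluded with a reason): the peak fraction's mean ribosome count divided by
the CDS length × 100. CDS length is used in place of transcript length,
which is typically unavailable for bacterial operons. Densities above
100/footprint = 3.33 ribosomes/100 nt (30-nt footprint) are physically
impossible and flagged aberrant; such genes are excluded downstream.

The engaged-ribosome percentage is a trace-level quantity: trapezoidal area
integration of the UV-absorbance profile over the free-subunit region vs the
monosome+polysome region.

## Two-condition comparison

Occupancy: two-sided two-sample Student test on the per-series values,
Welch's unequal-variance form by default (robust at n = 5 per group; the
pooled variant is a flag). Degenerate zero-variance samples are decided by
the mean difference with a 1e-12 floor that absorbs float jitter in exact
data. Density: the calibrated peak ribosome counts are discrete, so the
call is an exact comparison (the shared CDS length cancels). No
multiple-testing correction by default — the procedure is a per-gene
p < 0.05 — with Benjamini–Hochberg available as an option. The test is
unpaired: the two conditions come from independent cultures.

Class mapping: (higher|similar occupancy, higher density) → up;
(lower|similar, lower) → down; opposite directions → antagonistic;
(similar, similar) → unregulated. The (higher/lower occupancy, similar
density) cells cannot be forced into up/down honestly and are reported under
a distinct `occupancy-only` label; they are rare because density is almost
always changed.

## Rate decomposition and clustering

All rates are harmonized to min⁻¹ (half-lives arrive in minutes, growth
rates in h⁻¹). k_deg = ln2/t½; the dilution constant is the growth rate μ;
k_trans follows from the steady-state balance k_trans·copies = (k_deg+μ)·[mRNA]
with gene copies defaulting to 1 (assumed constant). Two identities are
enforced by tests: the steady-state balance to 1e-9 and k_deg ratio =
inverse half-life ratio exactly.

The per-gene stress/optimal ratios (k_trans, k_deg, μ, density, occupancy)
plus a constant reference column of 1 are clustered with Ward linkage on
Euclidean distance over the **raw** ratios — the display convention anchors
the colour scale at ratio 1, and log2 is offered as an option only. The tree
is cut at k = 6 clusters; labels are renumbered by decreasing size. Ward
agglomeration is deterministic given row order, and the result is invariant
to row permutation up to relabelling; a `seed` argument exists for interface
symmetry only. If fewer than k distinct merge heights exist (e.g. identical
rows), the result carries fewer clusters and is thereby flagged degenerate.

## Enrichment

Category enrichment is the hypergeometric upper tail P(X ≥ k) (one-sided
Fisher), the standard exact test for over-representation; uncategorized
genes pool as "unknown". The isoleucine codon-content check compares
per-gene ATT/ATC/ATA codon frequencies between a group and the remaining
genes with a two-sided Mann–Whitney test (exact permutation variant for
small groups). Raw p < 0.05 by default, BH optional, matching the
per-gene-threshold convention of the rest of the pipeline.

## The synthetic generator

What it emulates: a 1948-gene duplicate-spotted array design, five replicate
series, the two-condition gradient geometry above, empty spots drawn from
the background distribution (so the cutoff rule behaves as on real arrays),
multiplicative log-normal spot noise (default σ = 0.2) plus additive
Gaussian background, per-fraction total RNA composed of mRNA plus
ribosome-proportional rRNA mass, and UV traces as Gaussian peak sums with a
prescribed engaged-area share.

Each gene carries a regulation archetype with frequencies matching the
observed class sizes (39:420:356:1 of 816 for up:down:antagonistic:
unregulated). Loading distributions are discretized truncated normals
(width 0.7 fractions) centred on the archetype's peak: up genes move from
the monosome to the heaviest stress fraction; down/antagonistic genes sit in
the heavy optimal fractions (75% in the heaviest, mean 14 ribosomes) and
move strictly lighter under stress (biased to the 8.4-ribosome fraction);
antagonistic genes additionally gain 0.08–0.18 occupancy. "Similar"
occupancy is planted as exactly Δ = 0: the similarity band is |Δ| ≤ 0.02,
and a nonzero planted Δ with zero measurement noise would make any exact
test reject, so the zero-noise recovery oracle is attainable only at Δ = 0.
Half-lives are log-normal with population means 6.2 min (optimal) and
12.1 min (stress); mRNA levels are log-normal with stress levels ~0.6× the
optimal ones; ~12% of genes are silent (mRNA 0) to emulate the unexpressed
part of the array. CDS lengths are log-normal with median 960 nt in
[90, 6000], giving a realistic share of short genes whose top-fraction
density exceeds the 3.33 ceiling (the aberrant-filter path).

What it does **not** emulate: spatial array artifacts, print-tip or
hybridization-kinetics effects, gradient hydrodynamics, operon structure
(genes are independent), or condition-dependent rRNA-per-ribosome mass. A
consequence of the last point: the generator's mRNA share of total RNA is
*higher* under stress (fewer ribosomes per mRNA at equal rRNA mass per
ribosome), so the pipeline's mRNA-share ratio on synthetic data sits near
2.8 rather than the ~1 expected of real cells; the statistic is computed
and reported but carries no recovery claim. Passing recovery tests
demonstrate the estimators are correct under this noise model, not that real
arrays meet its assumptions.

## Problem sizes and numerics

The default pipeline profile runs the full design — 1948 genes × 5 series ×
(6 + 8) arrays — with 1000 bootstrap iterations, which completes in seconds;
10 000 iterations reproduce the same calls on synthetic data and are one
config field away. The bootstrap is vectorised over genes in chunks of 512
to bound memory. Stage seeds derive deterministically from the single run
seed; identical configs give byte-identical reports. Clustering benchmarks
use 900 genes over six planted ratio archetypes with additive ratio noise
σ = 0.1.

Known limitations: the optimal-condition ribosome calibration is a
placeholder (see above); the cutoff rule has limited power against
low-expression noise-only genes (false "expressed" calls are possible, as on
real arrays, and propagate as honestly noisy estimates); density resolution
is bounded by the fraction discretisation, so modest density changes within
a fraction are invisible to the density call.
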