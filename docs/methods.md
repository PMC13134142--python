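# Methods

`hicarch` implements the chromatin-architecture statistics used to follow
genome reorganization across an ordered series of cell states (its motivating
use case is terminal erythroid differentiation, BFU-E → CFU-E → ProE → EB →
LB → Poly → Ortho), together with a seeded synthetic-data generator that
stands in for access-controlled Hi-C data. This note records the models,
the defaults and why, and what the synthetic conditions do and do not show.

## Contact-matrix model

All analyses operate on a dense symmetric matrix over a global bin grid
(0-based, half-open coordinates; distance between bins is |i−j| ×
resolution, measured between bin starts). Self-pairs (the main diagonal)
are set to zero at simulation time and excluded from every statistic.
Masking removes bins whose raw marginal falls below a fraction of the median
marginal (default 0.1; the filtering rule ahead of balancing is a package
choice). Balancing is iterative proportional correction to equal marginals:
weights `w` with `balanced = w wᵀ ∘ counts` are iterated until the
coefficient of variation of unmasked marginals is below tolerance
(default 1e−7, max 2000 iterations; non-convergence raises rather than
returning partial output). The equal-marginal contract is the testable
property; KR factorization would satisfy the same contract.

The distance expectation is the mean balanced value per bin separation,
computed per chromosome over unmasked pairs; O/E divides by it. A single
genome-wide mean over unmasked trans pairs serves as the trans expectation.
Multiplying O/E back by the profile reconstructs the balanced matrix on
defined pairs, which the tests assert to float precision.

## Compartments

PC1 is the unit-norm leading eigenvector of the Pearson-correlation matrix
of O/E rows, computed per chromosome on unmasked bins (correlation rather
than covariance, so the result is scale-free; diagonal O/E entries are
treated as neutral 1 before correlating). The raw eigenvector sign is
arbitrary; orientation is automatic: the vector is flipped when it
anticorrelates with a reference track (planted truth for synthetic data, a
gene-density-like coverage track otherwise). This replaces manual curation
so runs are unattended and deterministic.

Bins with PC1 > 0 are A, < 0 are B, masked bins NA. Switching tables count
per-bin joint categories between consecutive stages; the switching fraction
is (A→B + B→A) over classified bins. Bins are uniform within a genome, so
the bin-count and bp conventions give the same fractions except for the
shorter terminal bin of each chromosome; NA bins are excluded from the
denominator and reported via `n_classified`.

Saddle plots rank bins by PC1 into equal-occupancy quantiles (default
Q = 50, corner fraction 0.2 — the published figures do not state a binning,
so these mirror common practice) and average cis O/E per quantile pair.
Quantile pairs with no cis pair (bins on different chromosomes) are NaN and
ignored in corner means. The scalar strength is
(mean AA corner + mean BB corner) / (2 × mean AB corner), a package
definition; being rank-based it is invariant under monotone rescaling of
PC1. Compartment contact ratios are log2 of the ratio of class-mean
observed values to class-mean expected values (distance profile for cis,
trans mean for trans), per A–A / B–B / A–B class.

## Distance scaling, DLR, ICF

P(s)-style curves sum cis pair values into logarithmic separation intervals.
The long-range fraction is the share of cis contacts strictly beyond a
cutoff (50 Mb default). DLR per bin is log2(distal / local) cis sums with a
3-Mb threshold; a pair at exactly the threshold is local ("within 3 Mb").
ICF per bin is the trans share of the bin's total contacts, in [0, 1]; the
formula is a package definition since the source analyses never write one.
DLR/ICF default to balanced values when present. Group comparisons
(e.g. DLR in A vs B bins) use the two-sided Wilcoxon rank-sum test; the
figures this mirrors report p-values without naming a test.

## TADs

The TAD-separation score at bin i is the mean contact between the w-bin
blocks immediately up- and downstream, z-scored per chromosome and averaged
across windows (defaults 150/250/500 kb at 50-kb resolution; the source
states "variable size" without listing windows). Bins closer than the
largest window to a chromosome edge are NaN. Boundaries are local minima
(leftmost bin of flat minima) whose depth below both nearest flanking maxima
is at least delta (0.01); domains form between consecutive boundaries and
are kept within [150 kb, 500 kb]. Oversized gaps still contribute their
boundaries.

Pileups rescale each domain window (left flank | domain | right flank,
flank 0.5 Mb) third-by-third onto a 90-pixel grid (30 per third) by
bilinear interpolation, so the central block always occupies pixels 30–59;
NaN entries (the matrix diagonal) are filled with neighbor means before
interpolation. Domain strength is log2(mean intra-domain O/E / mean O/E
between the domain and its equal-length flanks) — a package formula for a
term the source uses without defining. Stage dynamics report the per-domain
strength series and its relative variance (variance / |mean|). Inter-TAD
proportions divide inter-domain cis contacts per separation window
(including an open-ended > 80 Mb class) by total cis contacts.

A practical note verified on synthetic data: balancing redistributes part of
a planted intra-domain boost into the per-bin weights (domain bins get
systematically smaller weights), and a dense domain tiling pushes the boost
into the distance expectation. The closed-form identities (pileup central /
flank ≈ b, strength ≈ log2 b) therefore hold cleanly on raw-count O/E with
sparse planted domains, which is how the generator-truth tests are set up;
on balanced matrices the contrasts remain but are attenuated.

## Radial positioning of bead ensembles

Each model (one simulated nucleus; one bead per 1-Mb bin, two for diploid
models — homolog duplicates are averaged within a model) is processed
independently: center = centroid of valid bead coordinates; per-bead
distance = Euclidean norm to the center; nuclear radius = mean distance of
the farthest ⌈5%⌉ of beads (stable descending sort at ties). QC drops
models with fewer than 20 valid beads, then models whose radius deviates
from the ensemble mean by more than 3 SD (the source says only
"standard-deviation-based filtering"; the multiplier and the choice to
filter per-model radii rather than per-bead distances are package
interpretations, both configurable). Beads are classed center (< 20% of the
radius), peripheral (> 80%), else intermediate; boundary values are
intermediate, and relative distances above 1 are allowed and peripheral.
Classification uses each model's own radius, making it invariant under
rigid rotation and uniform scaling of a model; an ensemble-mean-radius mode
is available via the explicit `radius` argument. Ensemble profiles average
per-bin relative distances and class indicator fractions over models; bins
are LAD-flagged at ≥ 50% overlap with LAD intervals.

For a uniform ball the top-5% radius estimator converges to
15·R·(1 − 0.95^{4/3}) ≈ 0.992 R, giving expected peripheral and center
fractions (r/R̂ > 0.8 and < 0.2) of ≈ 0.50 and ≈ 0.008; the tests check
these against an independent rejection-sampling Monte-Carlo oracle.

## Interval enrichment

Overlap is measured in base pairs (scale-invariant, unlike interval
counts). Fold enrichment of state × feature is
(overlap/state bp) / (feature bp / genome bp), so a feature covering the
whole genome gives 1 and disjoint sets give 0. Track aggregation over
intervals is overlap-bp-weighted; interval sizes are summarized as log10 bp.

## Synthetic-data generator

Expected cis counts are multiplicative:
`E_ij = C · |i−j|^(−α) · (1 + s·p_i·p_j) · b^[same TAD] · λ^[sep > cutoff]`,
trans `E_ij = C · τ · (1 + s·p_i·p_j)`, with C scaling the expected total
over distinct pairs to the requested depth; realized counts are Poisson.
The multiplicative form is chosen for closed-form testability. Defaults:
α = 1 (a realistic contact-probability decay slope), compartment strength
s = 0.3–0.4 for signal stages (s < 1 keeps expectations positive), depth
10⁵–10⁷ per matrix depending on the analysis (desk-scale stand-ins for
billion-read libraries), toy genomes of 2–4 chromosomes of 100–500 bins so
that 50-Mb and 80-Mb cutoffs are exercisable.

The compartment profile is random-sign blocks per bin. A strictly
alternating ±1 profile would make p_i·p_j constant along every diagonal, so
the compartment factor would be absorbed entirely by the distance
expectation and O/E would be flat — random blocks avoid this degeneracy and
resemble real A/B tracks. Similarly, the per-diagonal-mean monotonicity of
the expectation holds for the decay and TAD components; the compartment
term adds bounded per-diagonal fluctuation from the profile's
autocorrelation.

Stage series share a profile except a seeded subset of exactly
round(f·nbins) bins flipped per transition (default f emulating the ≈ 2%
switching regime), with a direction parameter setting the A→B share of
flips to plant asymmetric switching. Bead ensembles place non-LAD beads
uniformly in a ball (r = R·U^{1/3}) and LAD beads with an outward tilt
(r = R·U^{1/(3+β)}, so β = 0 is uniform and the mean relative radius is
(3+β)/(4+β)). A configurable fraction of models is deliberately degraded
(alternately bead-starved below the QC minimum and radius-inflated 10×) to
exercise both QC rules.

What the generator does not emulate: restriction-fragment structure,
mappability/GC bias (so balancing weights are near-uniform by
construction), translocations or copy-number effects, distance-dependent
noise beyond Poisson, and the spatial polymer constraints behind real
Chrom3D models. Passing tests demonstrate algorithmic correctness and
recovery of planted structure at desk scale, not biological claims about
real erythroblast data.

## Problem sizes and numerics

Test and acceptance runs use toy genomes (≤ 2000 bins, ≤ 10⁵ beads per
ensemble block), chosen so the whole suite completes in well under a minute
of numerical work per criterion. Deterministic seeding is threaded through
every generator; pipeline TSVs are written with a fixed float format so a
rerun with the same config and seed is byte-identical. Degenerate inputs:
single-bin chromosomes yield empty distance profiles, not errors; constant
O/E rows make PC1 fail loudly; all-bins-masked and all-models-excluded
conditions raise; empty boundary sets are valid results.
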