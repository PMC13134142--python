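# hicarch

Stage-resolved Hi-C chromatin-architecture analysis. `hicarch` is a Python
library and CLI for following 3D genome reorganization across an ordered
series of cell states — its motivating application is terminal erythroid
differentiation (BFU-E → CFU-E → ProE → EB → LB → Poly → Ortho), where
chromatin condenses, B-compartment contacts strengthen, TAD boundaries
weaken, and heterochromatin repositions toward the nuclear lamina. Because
the primary human datasets in this area are access-controlled, the package
ships a seeded synthetic-data generator with planted ground truth, so every
analysis stage is testable end to end without any download.

## What it computes

For binned contact matrices (dense symmetric counts on a genome bin grid;
0-based half-open coordinates):

- **Balancing** — iterative proportional correction to equal marginals
  (weights `w` with `balancedᵢⱼ = wᵢ wⱼ countsᵢⱼ`), plus low-coverage bin
  masking; distance expectation and observed/expected (O/E) matrices;
  replicate Pearson correlation with sum-pooling to coarser bins.
- **A/B compartments** — per-chromosome PC1: the leading eigenvector of the
  Pearson-correlation matrix of O/E rows; A where PC1 > 0, B where PC1 < 0,
  with automatic sign orientation against a reference track. Stage-to-stage
  switching tables (A→A / A→B / B→A / B→B), saddle plots over PC1 quantiles
  with a scalar compartment strength
  `(mean AA corner + mean BB corner) / (2 · mean AB corner)`, and
  A–A/B–B/A–B log2 observed-vs-expected contact ratios (cis and trans).
- **Distance scaling** — P(s)-style contact-vs-distance curves on log
  intervals; the long-range contact fraction beyond a cutoff (default
  50 Mb); per-bin **DLR** = log2(cis contacts > 3 Mb / cis contacts ≤ 3 Mb)
  and **ICF** = a bin's trans share of its total contacts, with
  compartment-stratified summaries and Wilcoxon rank-sum tests.
- **TADs** — multi-window insulation score (mean contact across a bin
  between flanking blocks, z-scored per chromosome), boundary calling at
  sufficiently deep local minima (delta 0.01, domains 150–500 kb at 50-kb
  resolution), boundary-anchored pileups on a fixed 90-pixel grid, domain
  strength `log2(intra-domain O/E / domain-vs-flank O/E)` with its relative
  variance across stages, and inter-TAD contact proportions per distance
  window (including > 80 Mb).
- **Radial positioning** — for ensembles of simulated 3D nucleus bead
  models: per-model centroid and bead distances, nuclear radius = mean of
  the farthest 5% of beads, QC (≥ 20 valid beads; 3-SD radius outliers),
  three-way classification (center < 20%, peripheral > 80% of the radius),
  and per-1-Mb-bin ensemble profiles with a LAD overlay.
- **Interval enrichment** — bp-overlap fold enrichment of chromatin states
  against genomic features relative to the genome-wide composition, track
  aggregation over intervals, and interval-size distributions.

See `docs/methods.md` for the definitions, defaults and their rationale.

## Worked example

```python
import numpy as np
import hicarch as h

genome = h.GenomeSpec({"chr1": 120_000_000, "chr2": 80_000_000}, 1_000_000)
truth = h.random_compartment_profile(genome, block_bins=5, seed=0)
stage = h.StageSpec("LB", alpha=1.0, profile=truth, strength=0.4,
                    trans_level=0.02, depth=2_000_000, seed=0)
mat = h.simulate_contact_matrix(genome, stage)

mat = h.balance_matrix(h.mask_low_coverage(mat))
oe = h.observed_over_expected(mat)

# PC1 is called per chromosome and oriented against a reference track
pc1 = np.full(genome.nbins, np.nan)
for chrom in genome.chromosomes:
    sl = genome.chrom_slice(chrom)
    raw = h.compute_pc1(oe[sl, sl], valid=mat.mask[sl])
    pc1[sl], _ = h.orient_pc1(raw.values, truth[sl].astype(float))
labels = h.labels_from_pc1(pc1)

agreement = (labels == np.where(truth == 1, "A", "B")).mean()
sad = h.saddle(oe, pc1, n_quantiles=20)
print(f"label agreement with planted truth: {agreement:.1%}")
print(f"compartment strength (saddle):      {sad.strength:.3f}")
print(f"long-range fraction (>50 Mb):       {h.long_range_fraction(mat, 50_000_000):.4f}")
dlr = h.dlr(mat)
summary, p = h.stratify_track(dlr, labels, compare=("A", "B"))
print(f"mean DLR in A: {summary.set_index('group').loc['A','mean']:+.3f}   "
      f"in B: {summary.set_index('group').loc['B','mean']:+.3f}   (p = {p:.2g})")
print(f"mean ICF: {np.nanmean(h.icf(mat)):.4f}")
```

Output:

```
label agreement with planted truth: 100.0%
compartment strength (saddle):      2.259
long-range fraction (>50 Mb):       0.0440
mean DLR in A: +0.180   in B: -0.066   (p = 8.6e-06)
mean ICF: 0.1649
```

The simulated matrix carries a planted ±1 compartment profile of strength
s = 0.4; after balancing, O/E, per-chromosome PC1 and orientation, every
bin's A/B call matches the planted truth, and the saddle strength is well
above the null value of 1. The long-range fraction is the share of cis
contacts beyond 50 Mb under the α = 1 decay; DLR and ICF are the per-bin
distal-to-local log2 ratio and trans-contact share averaged over bins.

## Command line

The `hicarch` entry point exposes `simulate`, `balance`, `compartments`,
`scaling`, `tads`, `radial`, `enrich` and `run-all`. The pipeline runs from
a single YAML config (stages, genome, synthetic block or matrix paths,
parameter overrides, seed) and writes per-stage and cross-stage TSVs plus a
manifest with the config hash; a rerun with the same config and seed is
byte-identical.

```bash
hicarch run-all --config config.yaml --seed 7 --out results/
```

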