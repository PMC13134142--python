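"""Synthetic multi-stage Hi-C data with planted ground truth.

Stands in for restricted stage-resolved Hi-C data: contact matrices with
power-law distance decay, checkerboard (random-sign block) compartment
structure of tunable strength, planted TADs, long-range and trans contact
boosts, Poisson count noise; stage series with planted compartment
switching; bead ensembles uniform in a ball with LAD beads biased
peripherally; and BED/bedGraph annotation fixtures.  Every generator is
seeded and emits its planted truth alongside the data, so downstream
recovery is testable.

The expected-count model is multiplicative.  For cis bins ``i, j`` on one
chromosome::

    E_ij = C * |i-j|**(-alpha) * (1 + s * p_i * p_j) * b^[same TAD]
             * lam^[separation > cutoff]

and for trans pairs ``E_ij = C * tau * (1 + s * p_i * p_j)``, with ``C``
chosen so the expected total over distinct pairs equals the requested
sequencing depth.  Realized counts are Poisson with those means, symmetric,
zero diagonal.  The compartment profile ``p`` is ±1 per bin; the default
profile is random-sign blocks — for a strictly alternating profile the
compartment factor would be constant along each diagonal and absorbed into
the distance expectation, which is not what real A/B tracks look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import IntervalSet
from .genome import GenomeSpec
from .matrix import ContactMatrix
from .radial import BeadEnsemble, BeadModel, BEAD_COLUMNS


@dataclass
class StageSpec:
    """Parameters of one stage's synthetic contact matrix.

    alpha: distance-decay exponent (expected cis contact ∝ d^-alpha), > 0.
    profile: per-bin compartment sign ±1 (None → random blocks from seed).
    strength: compartment strength s, 0 ≤ s < 1.
    tads: list of (chrom, start_bp, end_bp) planted domains, non-overlapping.
    tad_boost: intra-domain multiplicative boost b > 1 (1 = none).
    longrange_boost: boost λ ≥ 1 for cis pairs separated by > cutoff.
    longrange_cutoff_bp: separation cutoff for λ.
    trans_level: relative trans contact level τ ≥ 0.
    depth: expected total count over distinct pairs.
    seed: RNG seed for both profile generation and Poisson sampling.
    """

    label: str
    alpha: float = 1.0
    profile: np.ndarray | None = None
    strength: float = 0.0
    tads: list[tuple[str, int, int]] = field(default_factory=list)
    tad_boost: float = 1.0
    longrange_boost: float = 1.0
    longrange_cutoff_bp: int = 50_000_000
    trans_level: float = 0.0
    depth: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 <= self.strength < 1):
            raise ValueError("compartment strength must satisfy 0 <= s < 1")
        if self.tad_boost < 1 or self.longrange_boost < 1:
            raise ValueError("boosts must be >= 1")
        if self.trans_level < 0:
            raise ValueError("trans level must be >= 0")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.tads:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"planted TADs overlap on {chrom}")


def random_compartment_profile(
    genome: GenomeSpec, block_bins: int = 10, seed: int = 0
) -> np.ndarray:
    """Random ±1 per-bin profile in blocks of ``block_bins`` per chromosome."""
    rng = np.random.default_rng(seed)
    out = np.empty(genome.nbins, dtype=np.int64)
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom)
        n = sl.stop - sl.start
        nblocks = -(-n // block_bins)
        signs = rng.choice([-1, 1], size=nblocks)
        out[sl] = np.repeat(signs, block_bins)[:n]
    return out


def plant_tads(
    genome: GenomeSpec,
    min_size_bp: int,
    max_size_bp: int,
    gap_bp: int,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Tile each chromosome with non-overlapping random-size domains."""
    rng = np.random.default_rng(seed)
    res = genome.resolution
    tads = []
    for chrom, length in genome.chromosomes.items():
        pos = gap_bp
        while pos + min_size_bp <= length - gap_bp:
            size = int(rng.integers(min_size_bp // res, max_size_bp // res + 1)) * res
            if pos + size > length - gap_bp:
                break
            tads.append((chrom, pos, pos + size))
            pos += size + gap_bp
    return tads


def _tad_id_per_bin(genome: GenomeSpec, tads: list[tuple[str, int, int]]) -> np.ndarray:
    """Per-bin planted-domain id (-1 outside any domain)."""
    ids = np.full(genome.nbins, -1, dtype=np.int64)
    res = genome.resolution
    for k, (chrom, s, e) in enumerate(tads):
        sl = genome.chrom_slice(chrom)
        first = sl.start + s // res
        last = sl.start + (e - 1) // res
        ids[first : last + 1] = k
    return ids


def expected_matrix(genome: GenomeSpec, stage: StageSpec) -> np.ndarray:
    """Closed-form expected count matrix (depth-scaled, zero diagonal)."""
    n = genome.nbins
    p = stage.profile
    if p is None:
        p = random_compartment_profile(genome, seed=stage.seed)
    p = np.asarray(p)
    if p.shape != (n,):
        raise ValueError("compartment profile length must match genome bin count")
    comp = 1.0 + stage.strength * np.outer(p, p)
    E = np.zeros((n, n))
    tad_ids = _tad_id_per_bin(genome, stage.tads)
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom)
        nc = sl.stop - sl.start
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            decay = np.where(d > 0, d ** (-stage.alpha), 0.0)
        block = decay * comp[sl, sl]
        ids = tad_ids[sl]
        same_tad = (ids[:, None] == ids[None, :]) & (ids[:, None] >= 0)
        block = np.where(same_tad, block * stage.tad_boost, block)
        far = d * genome.resolution > stage.longrange_cutoff_bp
        block = np.where(far, block * stage.longrange_boost, block)
        E[sl, sl] = block
    if stage.trans_level > 0:
        cis = np.zeros((n, n), dtype=bool)
        for chrom in genome.chromosomes:
            sl = genome.chrom_slice(chrom)
            cis[sl, sl] = True
        E[~cis] = stage.trans_level * comp[~cis]
    np.fill_diagonal(E, 0.0)
    total = np.triu(E, 1).sum()
    if total > 0:
        E *= stage.depth / total
    return E


def simulate_contact_matrix(genome: GenomeSpec, stage: StageSpec) -> ContactMatrix:
    """Poisson-sample a symmetric count matrix from the expected model."""
    E = expected_matrix(genome, stage)
    rng = np.random.default_rng(stage.seed)
    n = genome.nbins
    iu, ju = np.triu_indices(n, k=1)
    counts = np.zeros((n, n), dtype=np.int64)
    sampled = rng.poisson(E[iu, ju])
    counts[iu, ju] = sampled
    counts[ju, iu] = sampled
    return ContactMatrix(genome, counts)


# ---------------------------------------------------------------------------
# Stage series with planted compartment switching
# ---------------------------------------------------------------------------

SWITCH_CATEGORIES = ["A->A", "A->B", "B->A", "B->B"]


def simulate_stage_series(
    genome: GenomeSpec,
    stages: list[StageSpec],
    switch_fraction: float = 0.0,
    a_to_b_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[ContactMatrix], list[np.ndarray], pd.DataFrame]:
    """Simulate consecutive stages sharing a profile except planted switches.

    Between each consecutive stage pair, exactly ``round(switch_fraction *
    nbins)`` bins flip sign; a fraction ``a_to_b_fraction`` of the flips are
    drawn from currently-A (+1) bins (A→B) and the rest from B bins (B→A),
    allowing asymmetric switching.  Returns (matrices, per-stage profiles,
    truth table) where the truth table records per-bin per-transition planted
    categories.
    """
    if not stages:
        raise ValueError("empty stage list")
    if not (0 <= switch_fraction < 1):
        raise ValueError("switch_fraction must be in [0, 1)")
    n = genome.nbins
    base = stages[0].profile
    if base is None:
        base = random_compartment_profile(genome, seed=stages[0].seed)
    profiles = [np.asarray(base).copy()]
    rng = np.random.default_rng(seed)
    records = []
    bins = genome.bins()
    for t in range(1, len(stages)):
        prev = profiles[-1]
        cur = prev.copy()
        n_flip = round(switch_fraction * n)
        n_ab = round(a_to_b_fraction * n_flip)
        n_ba = n_flip - n_ab
        a_bins = np.flatnonzero(prev == 1)
        b_bins = np.flatnonzero(prev == -1)
        n_ab = min(n_ab, a_bins.size)
        n_ba = min(n_ba, b_bins.size)
        flip_ab = rng.choice(a_bins, size=n_ab, replace=False)
        flip_ba = rng.choice(b_bins, size=n_ba, replace=False)
        cur[flip_ab] = -1
        cur[flip_ba] = 1
        transition = f"{stages[t - 1].label}->{stages[t].label}"
        for i in range(n):
            cat = ("A" if prev[i] == 1 else "B") + "->" + ("A" if cur[i] == 1 else "B")
            records.append(
                {
                    "transition": transition,
                    "bin": i,
                    "chrom": bins["chrom"].iloc[i],
                    "start": int(bins["start"].iloc[i]),
                    "category": cat,
                }
            )
        profiles.append(cur)
    matrices = [
        simulate_contact_matrix(genome, replace(stage, profile=prof))
        for stage, prof in zip(stages, profiles)
    ]
    truth = pd.DataFrame(records, columns=["transition", "bin", "chrom", "start", "category"])
    return matrices, profiles, truth


# ---------------------------------------------------------------------------
# Bead ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Bead-ensemble generator parameters.

    One bead per 1-Mb bin of ``genome`` per model, placed uniformly at random
    in a ball of ``radius``; LAD-flagged beads get radial density tilted
    outward by ``peripheral_bias`` β (radius drawn as R·U^(1/(3+β)); β = 0
    reduces to uniform).  ``degraded_fraction`` of the models are emitted
    deliberately broken for QC testing: half with fewer than 20 valid beads,
    half with a 10× inflated radius.
    """

    n_models: int = 400
    genome: GenomeSpec | None = None
    radius: float = 1.0
    lad_flags: np.ndarray | None = None  # per-bin bool
    peripheral_bias: float = 0.0
    degraded_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("need at least one model")
        if self.peripheral_bias < 0:
            raise ValueError("peripheral bias must be >= 0")
        if not (0 <= self.degraded_fraction <= 1):
            raise ValueError("degraded fraction must be in [0, 1]")


def _sample_ball(rng: np.random.Generator, n: int, radius: float, beta: float) -> np.ndarray:
    """n points in a ball: uniform directions, r = R * U^(1/(3+beta))."""
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    r = radius * rng.uniform(size=n) ** (1.0 / (3.0 + beta))
    return vec * r[:, None]


def simulate_bead_ensemble(spec: EnsembleSpec) -> BeadEnsemble:
    """Generate a seeded bead ensemble per :class:`EnsembleSpec`."""
    genome = spec.genome
    if genome is None:
        genome = GenomeSpec({"chr1": 100_000_000}, 1_000_000)
    bins = genome.bins()
    n_beads = len(bins)
    lad = spec.lad_flags
    if lad is None:
        lad = np.zeros(n_beads, dtype=bool)
    lad = np.asarray(lad, bool)
    rng = np.random.default_rng(spec.seed)
    n_degraded = round(spec.degraded_fraction * spec.n_models)
    models = []
    for k in range(spec.n_models):
        coords = np.empty((n_beads, 3))
        coords[~lad] = _sample_ball(rng, int((~lad).sum()), spec.radius, 0.0)
        coords[lad] = _sample_ball(rng, int(lad.sum()), spec.radius, spec.peripheral_bias)
        df = pd.DataFrame(
            {
                "chrom": bins["chrom"],
                "start": bins["start"],
                "end": bins["end"],
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
            }
        )
        if k < n_degraded:
            if k % 2 == 0:
                # bead-starved: fewer than the QC minimum of valid positions
                df.loc[df.index[19:], ["x", "y", "z"]] = np.nan
            else:
                # inflated radius: flagged later by SD-based outlier filtering
                df[["x", "y", "z"]] *= 10.0
        df["valid"] = np.isfinite(df[["x", "y", "z"]].to_numpy(float)).all(axis=1)
        models.append(BeadModel(f"model_{k:04d}", df[BEAD_COLUMNS]))
    return BeadEnsemble(models)


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

STATE_LABELS = [f"state{k}" for k in range(1, 8)]
FEATURE_LABELS = ["CpG_island", "exon", "TSS", "TES", "intergenic"]


def make_annotation_fixture(
    genome: GenomeSpec, seed: int = 0, lad_shift: float = 0.5
) -> dict[str, object]:
    """Deterministic annotation fixtures on a toy genome.

    Emits non-overlapping chromatin-state intervals partitioning each
    chromosome, feature intervals per category, LAD intervals with sizes
    spanning at least one order of magnitude, and a per-bin log2-ratio track
    (lamin-style) elevated by ``lad_shift`` inside LADs.
    """
    rng = np.random.default_rng(seed)
    res = genome.resolution
    # chromatin states: random-length consecutive segments, labels cycled randomly
    state_rows = []
    for chrom, length in genome.chromosomes.items():
        pos = 0
        while pos < length:
            size = int(rng.integers(2, 9)) * res
            end = min(pos + size, length)
            state_rows.append((chrom, pos, end, STATE_LABELS[int(rng.integers(7))]))
            pos = end
    states = IntervalSet(
        pd.DataFrame(state_rows, columns=["chrom", "start", "end", "label"]),
        source="synthetic-states",
    )
    # features: per label, scattered non-overlapping intervals
    feat_rows = []
    for label in FEATURE_LABELS:
        for chrom, length in genome.chromosomes.items():
            pos = int(rng.integers(0, res))
            while pos < length - res:
                size = int(rng.integers(max(res // 10, 1), 2 * res))
                end = min(pos + size, length)
                if rng.uniform() < 0.4:
                    feat_rows.append((chrom, pos, end, label))
                pos = end + int(rng.integers(1, 4)) * res
    features = IntervalSet(
        pd.DataFrame(feat_rows, columns=["chrom", "start", "end", "label"]),
        source="synthetic-features",
    )
    # LADs: sizes cycled through a log-spaced ladder so they span ≥ one decade
    lad_rows = []
    ladder = res * np.array([1, 2, 5, 10, 20, 40])
    k = 0
    for chrom, length in genome.chromosomes.items():
        pos = int(rng.integers(0, 2 * res))
        while pos < length:
            size = int(ladder[k % len(ladder)]) + int(rng.integers(0, res // 2))
            k += 1
            end = min(pos + size, length)
            if end - pos >= res:
                lad_rows.append((chrom, pos, end, "LAD"))
            pos = end + int(rng.integers(2, 20)) * res
    lads = IntervalSet(
        pd.DataFrame(lad_rows, columns=["chrom", "start", "end", "label"]),
        source="synthetic-LADs",
    )
    # lamin-style per-bin log2 ratio track, elevated inside LADs
    bins = genome.bins()
    values = rng.normal(0.0, 0.25, size=len(bins))
    lad_frame = lads.intervals
    for k, b in enumerate(bins.itertuples(index=False)):
        sel = lad_frame[lad_frame["chrom"] == b.chrom]
        ov = np.clip(
            np.minimum(sel["end"], b.end) - np.maximum(sel["start"], b.start), 0, None
        ).sum()
        if ov >= 0.5 * (b.end - b.start):
            values[k] += lad_shift
    track = bins[["chrom", "start", "end"]].copy()
    track["value"] = values
    return {"states": states, "features": features, "lads": lads, "lamin_track": track}
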