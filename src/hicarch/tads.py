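"""Insulation scores, TAD boundary calling, pileups and domain dynamics.

The TAD-separation score at a bin is the mean contact between the
upstream and downstream blocks of a sliding window, z-scored per chromosome
and averaged across window sizes.  Local minima of this track whose depth
relative to the nearest flanking maxima exceeds a delta threshold are
boundaries; domains form between consecutive boundaries and are kept within
stated size bounds (defaults mirror 50-kb-resolution calling: windows
150/250/500 kb, domains 150-500 kb, delta 0.01).

Also here: boundary-anchored pileups of O/E windows rescaled to a fixed
pixel grid, per-domain strength (intra vs flank O/E log ratio) and its
relative variance across stages, and inter-TAD contact proportions per
genomic-distance window (with an open-ended > 80 Mb class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .genome import GenomeSpec
from .matrix import ContactMatrix

INSULATION_WINDOWS_BP = (150_000, 250_000, 500_000)
TAD_MIN_SIZE_BP = 150_000
TAD_MAX_SIZE_BP = 500_000
BOUNDARY_DELTA = 0.01
PILEUP_FLANK_BP = 500_000
PILEUP_PIXELS_PER_THIRD = 30


@dataclass
class InsulationTrack:
    """Per-bin separation score (z-score units) and the windows used."""

    values: np.ndarray
    window_sizes_bp: tuple[int, ...]


@dataclass
class TADSet:
    """Boundary bins with prominence and size-filtered domain intervals."""

    boundaries: pd.DataFrame  # chrom, bin (global), start, prominence
    domains: pd.DataFrame  # chrom, start, end (size within bounds)
    min_size_bp: int = TAD_MIN_SIZE_BP
    max_size_bp: int = TAD_MAX_SIZE_BP


# ---------------------------------------------------------------------------
# Insulation
# ---------------------------------------------------------------------------

def insulation_raw(
    matrix: ContactMatrix, window_bins: int, use: str = "auto"
) -> np.ndarray:
    """Un-normalized score: mean contact between the w-bin blocks flanking i.

    NaN for bins closer than ``window_bins`` to a chromosome edge; masked
    entries are excluded from the block mean.
    """
    vals = matrix.values(use).astype(float).copy()
    invalid = ~matrix.pair_valid()
    vals[invalid] = np.nan
    out = np.full(matrix.nbins, np.nan)
    for chrom in matrix.genome.chromosomes:
        sl = matrix.genome.chrom_slice(chrom)
        sub = vals[sl, sl]
        n = sub.shape[0]
        if window_bins >= n:
            raise ValueError(f"window larger than chromosome {chrom}")
        for i in range(window_bins, n - window_bins):
            block = sub[i - window_bins : i, i + 1 : i + 1 + window_bins]
            if np.isfinite(block).any():
                out[sl.start + i] = np.nanmean(block)
    return out


def insulation_score(
    matrix: ContactMatrix,
    window_sizes_bp: tuple[int, ...] = INSULATION_WINDOWS_BP,
    use: str = "auto",
) -> InsulationTrack:
    """Multi-window TAD-separation score: per-chromosome z-scores, averaged.

    Bins missing in any window (chromosome edges) are NaN in the final track,
    so the score is finite exactly on bins at least the largest window away
    from an edge.  Invariant to global rescaling of the matrix.
    """
    res = matrix.genome.resolution
    per_window = []
    for w_bp in window_sizes_bp:
        if w_bp % res != 0:
            raise ValueError("window sizes must be multiples of the resolution")
        raw = insulation_raw(matrix, w_bp // res, use=use)
        z = np.full_like(raw, np.nan)
        for chrom in matrix.genome.chromosomes:
            sl = matrix.genome.chrom_slice(chrom)
            seg = raw[sl]
            ok = np.isfinite(seg)
            if ok.sum() >= 2 and seg[ok].std() > 0:
                z[sl][ok] = (seg[ok] - seg[ok].mean()) / seg[ok].std()
            elif ok.any():
                z[sl][ok] = 0.0
        per_window.append(z)
    values = np.vstack(per_window).mean(axis=0)  # NaN if any window undefined
    return InsulationTrack(values, tuple(window_sizes_bp))


# ---------------------------------------------------------------------------
# Boundary calling
# ---------------------------------------------------------------------------

def _local_minima(t: np.ndarray) -> list[int]:
    """Indices of local minima (leftmost bin of flat minima) in a 1-D track."""
    minima = []
    n = len(t)
    for i in range(1, n - 1):
        if not (t[i] < t[i - 1] and t[i] <= t[i + 1]):
            continue
        # leftmost of a flat run: require the track to rise after the run
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        if j + 1 < n and t[j + 1] > t[i]:
            minima.append(i)
    return minima


def find_boundaries(
    track: InsulationTrack | np.ndarray,
    genome: GenomeSpec,
    delta: float = BOUNDARY_DELTA,
    min_size_bp: int = TAD_MIN_SIZE_BP,
    max_size_bp: int = TAD_MAX_SIZE_BP,
) -> TADSet:
    """Boundaries = sufficiently deep local minima; domains between them.

    A minimum qualifies when its depth below both nearest flanking maxima
    (the track maxima between it and the neighboring minima, or the finite
    region edge) is at least ``delta``.  Domains span consecutive boundary
    bins on a chromosome and are kept when their size is within
    [min_size_bp, max_size_bp].  Adding a constant to the track changes
    nothing.
    """
    values = track.values if isinstance(track, InsulationTrack) else np.asarray(track, float)
    res = genome.resolution
    brows, drows = [], []
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom)
        seg = values[sl]
        idx = np.flatnonzero(np.isfinite(seg))
        if idx.size < 3:
            continue
        kept = []
        # interior NaN gaps split the chromosome into independent finite runs
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if run.size < 3:
                continue
            lo, hi = run[0], run[-1] + 1
            t = seg[lo:hi]
            cand = [lo + i for i in _local_minima(t)]
            anchors = [lo - 1] + cand + [hi]
            for k, i in enumerate(cand):
                left_span = seg[anchors[k] + 1 : i]
                right_span = seg[i + 1 : anchors[k + 2]]
                left_max = left_span.max() if left_span.size else -np.inf
                right_max = right_span.max() if right_span.size else -np.inf
                depth = min(left_max - seg[i], right_max - seg[i])
                if depth >= delta:
                    kept.append((i, depth))
        for i, depth in kept:
            brows.append(
                {
                    "chrom": chrom,
                    "bin": sl.start + i,
                    "start": i * res,
                    "prominence": float(depth),
                }
            )
        for (i1, _), (i2, _) in zip(kept, kept[1:]):
            size = (i2 - i1) * res
            if min_size_bp <= size <= max_size_bp:
                drows.append({"chrom": chrom, "start": i1 * res, "end": i2 * res})
    boundaries = pd.DataFrame(brows, columns=["chrom", "bin", "start", "prominence"])
    domains = pd.DataFrame(drows, columns=["chrom", "start", "end"])
    return TADSet(boundaries, domains, min_size_bp, max_size_bp)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def _fill_diagonal_nans(w: np.ndarray) -> np.ndarray:
    """Replace NaN entries by the mean of finite orthogonal neighbors."""
    out = w.copy()
    bad = np.argwhere(~np.isfinite(out))
    overall = np.nanmean(out) if np.isfinite(out).any() else 1.0
    for i, j in bad:
        neigh = []
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            a, b = i + di, j + dj
            if 0 <= a < out.shape[0] and 0 <= b < out.shape[1] and np.isfinite(w[a, b]):
                neigh.append(w[a, b])
        out[i, j] = np.mean(neigh) if neigh else overall
    return out


def _thirds_coordinates(n_left: int, n_mid: int, n_right: int, px: int) -> np.ndarray:
    """Fractional source coordinates mapping each window third to px pixels."""
    def seg(start: float, length: int) -> np.ndarray:
        return start + (np.arange(px) + 0.5) * length / px - 0.5

    return np.concatenate(
        [seg(0, n_left), seg(n_left, n_mid), seg(n_left + n_mid, n_right)]
    )


def tad_pileup(
    oe: np.ndarray,
    genome: GenomeSpec,
    domains: pd.DataFrame,
    flank_bp: int = PILEUP_FLANK_BP,
    pixels_per_third: int = PILEUP_PIXELS_PER_THIRD,
) -> tuple[np.ndarray, list[str]]:
    """Average O/E map over domain windows rescaled to a fixed grid.

    Each window (left flank | domain | right flank) is rescaled third-by-
    third to ``pixels_per_third`` pixels each by bilinear interpolation, so
    the central block always spans pixels [P, 2P).  Domains whose window
    leaves the chromosome are skipped; their ids are returned.
    """
    if len(domains) == 0:
        raise ValueError("need at least one domain")
    res = genome.resolution
    fb = flank_bp // res
    px = pixels_per_third
    stack, skipped = [], []
    for _, dom in domains.iterrows():
        sl = genome.chrom_slice(dom["chrom"])
        d0 = int(dom["start"]) // res
        d1 = int(dom["end"]) // res
        nchrom = sl.stop - sl.start
        if d0 - fb < 0 or d1 + fb > nchrom:
            skipped.append(f"{dom['chrom']}:{dom['start']}-{dom['end']}")
            continue
        w = oe[sl, sl][d0 - fb : d1 + fb, d0 - fb : d1 + fb]
        w = _fill_diagonal_nans(w)
        coords = _thirds_coordinates(fb, d1 - d0, fb, px)
        coords = np.clip(coords, 0, w.shape[0] - 1)
        interp = RegularGridInterpolator(
            (np.arange(w.shape[0]), np.arange(w.shape[1])), w, method="linear"
        )
        gi, gj = np.meshgrid(coords, coords, indexing="ij")
        stack.append(interp(np.stack([gi.ravel(), gj.ravel()], axis=1)).reshape(3 * px, 3 * px))
    if not stack:
        raise ValueError("all domains skipped (windows leave chromosome)")
    return np.mean(stack, axis=0), skipped


def insulation_pileup(
    track: InsulationTrack | np.ndarray,
    boundaries: pd.DataFrame,
    flank_bins: int = 10,
) -> np.ndarray:
    """Average insulation profile anchored at boundary bins (± flank)."""
    values = track.values if isinstance(track, InsulationTrack) else np.asarray(track, float)
    rows = []
    for b in boundaries["bin"]:
        if b - flank_bins >= 0 and b + flank_bins < len(values):
            rows.append(values[b - flank_bins : b + flank_bins + 1])
    if not rows:
        raise ValueError("no boundary fits within the track")
    return np.nanmean(np.vstack(rows), axis=0)


# ---------------------------------------------------------------------------
# Domain strength and dynamics
# ---------------------------------------------------------------------------

def domain_strength(oe: np.ndarray, genome: GenomeSpec, domain: pd.Series | dict) -> float:
    """log2(mean intra-domain O/E / mean O/E between domain and its flanks).

    Flanks are the equal-length windows immediately up- and downstream;
    raises if they fall outside the chromosome.
    """
    res = genome.resolution
    sl = genome.chrom_slice(domain["chrom"])
    d0 = int(domain["start"]) // res
    d1 = int(domain["end"]) // res
    size = d1 - d0
    nchrom = sl.stop - sl.start
    if d0 - size < 0 or d1 + size > nchrom:
        raise ValueError("flanks unavailable at chromosome edge")
    sub = oe[sl, sl]
    intra = sub[d0:d1, d0:d1]
    between = np.concatenate(
        [sub[d0:d1, d0 - size : d0].ravel(), sub[d0:d1, d1 : d1 + size].ravel()]
    )
    intra_vals = intra[np.isfinite(intra)]
    between_vals = between[np.isfinite(between)]
    if intra_vals.size == 0 or between_vals.size == 0:
        return float("nan")
    return float(np.log2(intra_vals.mean() / between_vals.mean()))


def strength_dynamics(
    oe_per_stage: list[np.ndarray],
    genome: GenomeSpec,
    domains: pd.DataFrame,
    stage_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-domain strength series across stages plus relative variance.

    Domains are shared across stages (define them in one reference stage).
    Relative variance = variance of the per-stage strengths divided by the
    absolute mean; domains whose flanks leave the chromosome are dropped.
    """
    if stage_labels is None:
        stage_labels = [f"stage{k}" for k in range(len(oe_per_stage))]
    rows = []
    for _, dom in domains.iterrows():
        try:
            series = [domain_strength(oe, genome, dom) for oe in oe_per_stage]
        except ValueError:
            continue
        arr = np.array(series)
        mean = arr.mean()
        relvar = float(arr.var() / abs(mean)) if mean != 0 else float("nan")
        row = {"chrom": dom["chrom"], "start": dom["start"], "end": dom["end"]}
        row.update({lab: s for lab, s in zip(stage_labels, series)})
        row["relative_variance"] = relvar
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inter-TAD distance-window proportions
# ---------------------------------------------------------------------------

def inter_tad_distance_proportions(
    matrix: ContactMatrix,
    domains: pd.DataFrame,
    window_edges_bp: tuple[int, ...] = (0, 20_000_000, 50_000_000, 80_000_000),
    use: str = "auto",
) -> pd.DataFrame:
    """Share of total cis contacts that are inter-TAD, per separation window.

    An inter-TAD pair has its two bins in two different domains.  Windows are
    (edge_k, edge_{k+1}] plus an open-ended class above the last edge.
    """
    edges = list(window_edges_bp)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("window edges must be increasing")
    res = matrix.genome.resolution
    dom_id = np.full(matrix.nbins, -1, dtype=np.int64)
    for k, (_, dom) in enumerate(domains.iterrows()):
        sl = matrix.genome.chrom_slice(dom["chrom"])
        a = sl.start + int(dom["start"]) // res
        b = sl.start + int(dom["end"] - 1) // res
        if (dom_id[a : b + 1] >= 0).any():
            raise ValueError("overlapping domains")
        dom_id[a : b + 1] = k
    vals = matrix.values(use)
    sep = matrix.separation_bp()
    cis_pairs = np.triu(matrix.pair_valid(), k=1) & (sep > 0)
    total = vals[cis_pairs].sum()
    inter = (
        cis_pairs
        & (dom_id[:, None] >= 0)
        & (dom_id[None, :] >= 0)
        & (dom_id[:, None] != dom_id[None, :])
    )
    rows = []
    bounds = list(zip(edges, edges[1:])) + [(edges[-1], None)]
    for lo, hi in bounds:
        in_win = inter & (sep > lo)
        if hi is not None:
            in_win &= sep <= hi
        amount = vals[in_win].sum()
        rows.append(
            {
                "dist_lo_bp": lo,
                "dist_hi_bp": hi if hi is not None else -1,
                "proportion": float(amount / total) if total > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
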