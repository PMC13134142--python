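"""A/B compartment calling and compartment-level contact statistics.

The leading eigenvector (PC1) of the Pearson-correlation matrix of O/E rows
partitions each chromosome into A (positive) and B (negative) compartments.
Sign is oriented automatically against a reference track (gene-density-like
or planted truth), replacing manual curation.  Downstream: stage-to-stage
switching tables, saddle plots with a scalar compartment strength, and
A-A/B-B/A-B observed-vs-expected log ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix, ExpectedProfile, expected_by_distance

SADDLE_QUANTILES = 50
SADDLE_CORNER_FRACTION = 0.2


@dataclass
class PC1Result:
    """Raw per-bin eigenvector (NaN at masked bins) and eigenvalue share."""

    values: np.ndarray
    eigenvalue_fraction: float


def compute_pc1(oe: np.ndarray, valid: np.ndarray | None = None) -> PC1Result:
    """Leading eigenvector of the correlation matrix of O/E rows.

    ``oe`` is one chromosome's O/E matrix (NaN on the diagonal and at masked
    bins).  The Pearson correlation of rows is formed over unmasked bins
    (diagonal O/E treated as neutral 1), and the unit-norm eigenvector of the
    largest eigenvalue is returned, embedded with NaN at masked bins.  The
    eigenvalue fraction is the leading eigenvalue over the trace.
    """
    n = oe.shape[0]
    if valid is None:
        valid = ~np.all(np.isnan(oe), axis=0)
    if valid.sum() < 3:
        raise ValueError("need at least 3 unmasked bins")
    sub = oe[np.ix_(valid, valid)].copy()
    sub[np.isnan(sub)] = 1.0
    if np.any(sub.std(axis=1) == 0):
        raise ValueError("degenerate O/E matrix: constant rows")
    corr = np.corrcoef(sub)
    eigvals, eigvecs = np.linalg.eigh(corr)
    vec = eigvecs[:, -1]
    # deterministic raw sign (biological sign set later by orient_pc1)
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    values = np.full(n, np.nan)
    values[valid] = vec
    return PC1Result(values, float(eigvals[-1] / np.trace(corr)))


def orient_pc1(values: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip the eigenvector if it anticorrelates with a reference track.

    Returns (oriented values, flipped flag).  The reference must have
    variance over the bins where both are defined.
    """
    both = np.isfinite(values) & np.isfinite(reference)
    ref = np.asarray(reference, float)[both]
    if ref.std() == 0:
        raise ValueError("zero-variance reference track")
    r = np.corrcoef(values[both], ref)[0, 1]
    if r < 0:
        return -values, True
    return values, False


def labels_from_pc1(values: np.ndarray) -> np.ndarray:
    """Per-bin label: A (PC1 > 0), B (PC1 < 0), NA otherwise."""
    out = np.full(values.shape, "NA", dtype=object)
    out[np.nan_to_num(values, nan=0.0) > 0] = "A"
    out[np.nan_to_num(values, nan=0.0) < 0] = "B"
    return out


# ---------------------------------------------------------------------------
# Switching
# ---------------------------------------------------------------------------

@dataclass
class SwitchTable:
    """Joint A/B classification of bins across one stage transition."""

    categories: np.ndarray  # per-bin 'A->A' | 'A->B' | 'B->A' | 'B->B' | 'NA'
    counts: dict[str, int]
    fractions: dict[str, float]  # over classified bins
    switching_fraction: float  # (A->B + B->A) / classified
    n_classified: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "count": self.counts[c], "fraction": self.fractions[c]}
            for c in ("A->A", "A->B", "B->A", "B->B")
        ]
        return pd.DataFrame(rows)


def classify_switching(labels_a: np.ndarray, labels_b: np.ndarray) -> SwitchTable:
    """Per-bin joint category between two label tracks on identical bins."""
    labels_a = np.asarray(labels_a, dtype=object)
    labels_b = np.asarray(labels_b, dtype=object)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label tracks are on different bin grids")
    cats = np.full(labels_a.shape, "NA", dtype=object)
    ok = (labels_a != "NA") & (labels_b != "NA")
    cats[ok] = np.char.add(
        np.char.add(labels_a[ok].astype(str), "->"), labels_b[ok].astype(str)
    )
    n = int(ok.sum())
    counts = {c: int((cats == c).sum()) for c in ("A->A", "A->B", "B->A", "B->B")}
    fractions = {c: (counts[c] / n if n else float("nan")) for c in counts}
    switching = (counts["A->B"] + counts["B->A"]) / n if n else float("nan")
    return SwitchTable(cats, counts, fractions, switching, n)


# ---------------------------------------------------------------------------
# Saddle plots and compartment strength
# ---------------------------------------------------------------------------

@dataclass
class SaddleResult:
    """Q×Q mean O/E by ascending PC1 quantile plus the scalar strength.

    Strength = (mean of the BB corner + mean of the AA corner) /
    (2 × mean of the two AB corners); corners span the extreme
    ``corner_fraction`` of quantiles.  Rank-based, so invariant under any
    monotone rescaling of PC1.
    """

    matrix: np.ndarray
    strength: float
    n_quantiles: int
    corner_quantiles: int


def saddle(
    oe: np.ndarray,
    track: np.ndarray,
    n_quantiles: int = SADDLE_QUANTILES,
    corner_fraction: float = SADDLE_CORNER_FRACTION,
) -> SaddleResult:
    if n_quantiles < 2:
        raise ValueError("need at least 2 quantiles")
    finite = np.isfinite(track)
    idx = np.flatnonzero(finite)
    if idx.size < n_quantiles:
        raise ValueError("fewer defined bins than quantiles")
    order = idx[np.argsort(track[finite], kind="stable")]
    groups = np.array_split(order, n_quantiles)
    if any(g.size == 0 for g in groups):
        raise ValueError("empty quantile after masking")
    S = np.full((n_quantiles, n_quantiles), np.nan)
    for q, gq in enumerate(groups):
        for r in range(q, n_quantiles):
            block = oe[np.ix_(gq, groups[r])]
            vals = block[np.isfinite(block)]
            # a cell with no cis pair (bins on different chromosomes) is NaN
            if vals.size:
                S[q, r] = S[r, q] = vals.mean()
    k = math.ceil(corner_fraction * n_quantiles)
    bb = np.nanmean(S[:k, :k])
    aa = np.nanmean(S[-k:, -k:])
    ab = (np.nanmean(S[:k, -k:]) + np.nanmean(S[-k:, :k])) / 2.0
    return SaddleResult(S, float((aa + bb) / (2.0 * ab)), n_quantiles, k)


# ---------------------------------------------------------------------------
# Compartment contact ratios
# ---------------------------------------------------------------------------

def compartment_contact_ratio(
    matrix: ContactMatrix,
    labels: np.ndarray,
    scope: str = "cis",
    profile: ExpectedProfile | None = None,
    use: str = "auto",
) -> dict[str, float]:
    """log2 observed-vs-expected contact for A-A, B-B and A-B pairs.

    For each class, the ratio of the mean observed value over pairs in the
    class to the mean distance-expected value over those same pairs (cis) or
    to the genome-wide trans expectation (trans).  Classes with no pairs get
    NaN.
    """
    if scope not in ("cis", "trans"):
        raise ValueError("scope must be 'cis' or 'trans'")
    if profile is None:
        profile = expected_by_distance(matrix, use=use)
    vals = matrix.values(use)
    labels = np.asarray(labels, dtype=object)
    pairable = matrix.pair_valid()
    cis = matrix.cis_mask()
    sep = matrix.separation_bp()
    res = matrix.genome.resolution
    is_a = labels == "A"
    is_b = labels == "B"
    classes = {
        "AA": np.outer(is_a, is_a),
        "BB": np.outer(is_b, is_b),
        "AB": np.outer(is_a, is_b) | np.outer(is_b, is_a),
    }
    # expected value per pair
    n = matrix.nbins
    expmat = np.full((n, n), np.nan)
    if scope == "cis":
        for chrom in matrix.genome.chromosomes:
            sl = matrix.genome.chrom_slice(chrom)
            nc = sl.stop - sl.start
            d = np.abs(np.subtract.outer(np.arange(nc), np.arange(nc)))
            prof = profile.per_chrom[chrom]
            expmat[sl, sl] = np.where(d > 0, prof[d], np.nan)
        region = pairable & cis & (sep > 0)
    else:
        expmat[:] = profile.trans_mean
        region = pairable & ~cis
    out = {}
    for name, cls in classes.items():
        sel = region & cls & np.isfinite(expmat)
        if not sel.any():
            out[name] = float("nan")
            continue
        out[name] = float(np.log2(vals[sel].mean() / expmat[sel].mean()))
    return out
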