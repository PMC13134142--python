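"""Distance-stratified contact statistics.

P(s)-style contact-frequency-vs-distance curves on logarithmic separation
intervals, long-range contact fractions above a bp cutoff, per-bin DLR
(distal-to-local log2 ratio at a 3-Mb threshold) and ICF (a bin's trans
share of its total contacts), plus compartment-stratified summaries with a
rank-based two-group test.

Separation is measured between bin starts (|i-j| × resolution); a pair at
exactly the DLR threshold counts as local.  Masked bins are excluded from
all sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import rank_compare
from .matrix import ContactMatrix

DLR_THRESHOLD_BP = 3_000_000
LONG_RANGE_CUTOFF_BP = 50_000_000


@dataclass
class DistanceCurve:
    """Total contact per logarithmic separation interval (bp edges)."""

    edges_bp: np.ndarray  # length nbins+1, increasing
    totals: np.ndarray
    normalized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dist_lo_bp": self.edges_bp[:-1].astype(np.int64),
                "dist_hi_bp": self.edges_bp[1:].astype(np.int64),
                "total": self.totals,
            }
        )


def contact_frequency_vs_distance(
    matrix: ContactMatrix,
    n_log_bins: int = 20,
    use: str = "auto",
    normalize: bool = False,
) -> DistanceCurve:
    """Sum cis pair values into logarithmic separation intervals.

    Intervals span [resolution, max separation]; each distinct unmasked cis
    pair contributes once.  With ``normalize`` the totals are scaled to sum
    to 1.
    """
    if n_log_bins < 2:
        raise ValueError("need at least 2 log bins")
    vals = matrix.values(use)
    sep = matrix.separation_bp()
    sel = np.triu(matrix.pair_valid(), k=1) & (sep > 0)
    seps = sep[sel].astype(float)
    v = vals[sel].astype(float)
    lo = matrix.genome.resolution
    hi = seps.max()
    edges = np.geomspace(lo, hi, n_log_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max separation
    which = np.digitize(seps, edges) - 1
    totals = np.zeros(n_log_bins)
    np.add.at(totals, which, v)
    if normalize and totals.sum() > 0:
        totals = totals / totals.sum()
    return DistanceCurve(edges, totals, normalize)


def long_range_fraction(
    matrix: ContactMatrix, cutoff_bp: int = LONG_RANGE_CUTOFF_BP, use: str = "auto"
) -> float:
    """Share of cis contacts with separation strictly greater than the cutoff."""
    vals = matrix.values(use)
    sep = matrix.separation_bp()
    sel = np.triu(matrix.pair_valid(), k=1) & (sep > 0)
    total = vals[sel].sum()
    if total == 0:
        return float("nan")
    far = vals[sel & (sep > cutoff_bp)].sum()
    return float(far / total)


def dlr(
    matrix: ContactMatrix, threshold_bp: int = DLR_THRESHOLD_BP, use: str = "auto"
) -> np.ndarray:
    """Per-bin distal-to-local log2 ratio.

    DLR_i = log2(Σ cis contacts of bin i at separation > threshold /
    Σ cis contacts at 0 < separation ≤ threshold).  NaN where either sum is
    zero or the bin is masked.
    """
    if threshold_bp < matrix.genome.resolution:
        raise ValueError("threshold must be at least one bin")
    vals = matrix.values(use)
    sep = matrix.separation_bp()
    valid_pair = matrix.pair_valid()
    local = valid_pair & (sep > 0) & (sep <= threshold_bp)
    distal = valid_pair & (sep > threshold_bp)
    local_sum = np.where(local, vals, 0.0).sum(axis=1)
    distal_sum = np.where(distal, vals, 0.0).sum(axis=1)
    out = np.full(matrix.nbins, np.nan)
    ok = matrix.mask & (local_sum > 0) & (distal_sum > 0)
    out[ok] = np.log2(distal_sum[ok] / local_sum[ok])
    return out


def icf(matrix: ContactMatrix, use: str = "auto") -> np.ndarray:
    """Per-bin interchromosomal contact fraction: trans / (cis + trans).

    NaN where the bin's total is zero or the bin is masked.
    """
    vals = matrix.values(use)
    valid_pair = matrix.pair_valid()
    cis = matrix.cis_mask()
    trans_sum = np.where(valid_pair & ~cis, vals, 0.0).sum(axis=1)
    total_sum = np.where(valid_pair, vals, 0.0).sum(axis=1)
    out = np.full(matrix.nbins, np.nan)
    ok = matrix.mask & (total_sum > 0)
    out[ok] = trans_sum[ok] / total_sum[ok]
    return out


def stratify_track(
    track: np.ndarray,
    labels: np.ndarray,
    compare: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-group summary of a per-bin score, with an optional two-group test.

    Groups are the distinct label values over bins where the track is
    defined.  ``compare`` names two groups for a two-sided Wilcoxon rank-sum
    test; returns (summary frame, p-value or None).
    """
    track = np.asarray(track, float)
    labels = np.asarray(labels, dtype=object)
    ok = np.isfinite(track)
    rows = []
    for g in sorted({str(x) for x in labels[ok]}):
        v = track[ok & (labels == g)]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 defined values")
        rows.append(
            {
                "group": g,
                "n": int(v.size),
                "mean": float(v.mean()),
                "median": float(np.median(v)),
                "std": float(v.std(ddof=1)),
            }
        )
    summary = pd.DataFrame(rows)
    pvalue = None
    if compare is not None:
        a = track[ok & (labels == compare[0])]
        b = track[ok & (labels == compare[1])]
        _, pvalue = rank_compare(a, b)
    return summary, pvalue
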