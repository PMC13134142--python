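"""Binned contact matrices: IO, masking, balancing, expected/O-E, correlation.

The in-memory model is a dense symmetric matrix over the global bin grid of a
:class:`~hicarch.genome.GenomeSpec` (desk-scale genomes; a few thousand bins).
Raw counts are integers; balancing produces a real-valued matrix together with
per-bin weights ``w`` such that ``balanced[i, j] = w[i] * w[j] * counts[i, j]``.
Masked bins carry undefined weights and are excluded from every statistic.

Two on-disk dialects are supported: a sparse bin-pair text dump
(``chrom1 start1 chrom2 start2 count``, 0-based half-open starts, upper
triangle sufficient) and an NPZ binned container that round-trips counts,
balanced values, weights and mask losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec

SPARSE_COLUMNS = ["chrom1", "start1", "chrom2", "start2", "count"]


@dataclass
class ContactMatrix:
    genome: GenomeSpec
    counts: np.ndarray  # raw symmetric counts, zero diagonal
    balanced: np.ndarray | None = None
    weights: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # True = valid bin

    def __post_init__(self) -> None:
        n = self.genome.nbins
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match genome bin count")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    @property
    def nbins(self) -> int:
        return self.genome.nbins

    def values(self, use: str = "auto") -> np.ndarray:
        """Matrix values: 'raw', 'balanced', or 'auto' (balanced if present)."""
        if use == "raw":
            return self.counts
        if use == "balanced":
            if self.balanced is None:
                raise ValueError("matrix is not balanced")
            return self.balanced
        if use == "auto":
            return self.balanced if self.balanced is not None else self.counts
        raise ValueError(f"unknown mode {use!r}")

    def cis_mask(self) -> np.ndarray:
        """Boolean matrix: True where both bins lie on the same chromosome."""
        n = self.nbins
        out = np.zeros((n, n), dtype=bool)
        for chrom in self.genome.chromosomes:
            sl = self.genome.chrom_slice(chrom)
            out[sl, sl] = True
        return out

    def pair_valid(self) -> np.ndarray:
        """True where both bins are unmasked and i != j."""
        v = np.outer(self.mask, self.mask)
        np.fill_diagonal(v, False)
        return v

    def separation_bp(self) -> np.ndarray:
        """|i-j| * resolution within chromosomes; -1 for trans pairs."""
        n = self.nbins
        out = np.full((n, n), -1, dtype=np.int64)
        res = self.genome.resolution
        for chrom in self.genome.chromosomes:
            sl = self.genome.chrom_slice(chrom)
            idx = np.arange(sl.stop - sl.start)
            out[sl, sl] = np.abs(idx[:, None] - idx[None, :]) * res
        return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_matrix(matrix: ContactMatrix, path: str, dialect: str = "container") -> None:
    if dialect == "container":
        chroms = list(matrix.genome.chromosomes)
        np.savez(
            path,
            chrom_names=np.array(chroms, dtype=object),
            chrom_lengths=np.array([matrix.genome.chromosomes[c] for c in chroms]),
            resolution=matrix.genome.resolution,
            counts=matrix.counts,
            balanced=(matrix.balanced if matrix.balanced is not None else np.array([])),
            weights=(matrix.weights if matrix.weights is not None else np.array([])),
            mask=matrix.mask,
        )
    elif dialect == "sparse":
        bins = matrix.genome.bins()
        iu, ju = np.nonzero(np.triu(matrix.counts))
        df = pd.DataFrame(
            {
                "chrom1": bins["chrom"].to_numpy()[iu],
                "start1": bins["start"].to_numpy()[iu],
                "chrom2": bins["chrom"].to_numpy()[ju],
                "start2": bins["start"].to_numpy()[ju],
                "count": matrix.counts[iu, ju].astype(np.int64),
            }
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_matrix(
    path: str, dialect: str = "container", genome: GenomeSpec | None = None
) -> ContactMatrix:
    """Read a contact matrix.

    The sparse text dialect needs a ``genome`` to define the bin grid; records
    may list only the upper triangle and are symmetrized in memory.
    """
    if dialect == "container":
        with np.load(path, allow_pickle=True) as z:
            g = GenomeSpec(
                dict(zip(z["chrom_names"].tolist(), z["chrom_lengths"].tolist())),
                int(z["resolution"]),
            )
            balanced = z["balanced"] if z["balanced"].size else None
            weights = z["weights"] if z["weights"].size else None
            return ContactMatrix(g, z["counts"], balanced, weights, z["mask"])
    if dialect == "sparse":
        if genome is None:
            raise ValueError("sparse dialect requires a genome")
        df = pd.read_csv(path, sep="\t")
        missing = set(SPARSE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"malformed sparse file, missing columns {missing}")
        n = genome.nbins
        counts = np.zeros((n, n), dtype=np.int64)
        for c1, s1, c2, s2, v in df.itertuples(index=False):
            i = genome.bin_index(c1, int(s1))
            j = genome.bin_index(c2, int(s2))
            counts[i, j] += int(v)
            if i != j:
                counts[j, i] += int(v)
        np.fill_diagonal(counts, 0)
        return ContactMatrix(genome, counts)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Masking and balancing
# ---------------------------------------------------------------------------

def mask_low_coverage(
    matrix: ContactMatrix, min_fraction_of_median: float = 0.1
) -> ContactMatrix:
    """Mask bins whose raw marginal sum falls below a fraction of the median.

    The median is taken over currently-unmasked bins; masking is idempotent
    and only ever removes bins.  A threshold of 0 leaves the mask unchanged.
    """
    marg = matrix.counts.sum(axis=1).astype(float)
    current = matrix.mask
    med = np.median(marg[current])
    new_mask = current & (marg >= min_fraction_of_median * med)
    if min_fraction_of_median == 0:
        new_mask = current.copy()
    if not new_mask.any():
        raise ValueError("all bins would be masked")
    return replace(matrix, mask=new_mask)


def balance_matrix(
    matrix: ContactMatrix, tolerance: float = 1e-7, max_iterations: int = 2000
) -> ContactMatrix:
    """Iterative proportional correction to equal marginals on unmasked bins.

    Finds per-bin weights ``w`` with ``balanced = w w^T ∘ counts`` such that
    the coefficient of variation of the unmasked marginals is ≤ ``tolerance``.
    Raises if the iteration does not converge — never returns partial output.
    """
    valid = matrix.mask
    sub = matrix.counts[np.ix_(valid, valid)].astype(float)
    if sub.sum() == 0:
        raise ValueError("cannot balance an all-zero matrix")
    b = np.ones(sub.shape[0])
    converged = False
    for _ in range(max_iterations):
        cur = sub / np.outer(b, b)
        m = cur.sum(axis=1)
        cv = m.std() / m.mean()
        if cv <= tolerance:
            converged = True
            break
        m_norm = m / m.mean()
        m_norm[m_norm == 0] = 1.0
        b *= np.sqrt(m_norm)
    if not converged:
        cur = sub / np.outer(b, b)
        m = cur.sum(axis=1)
        if m.std() / m.mean() > tolerance:
            raise RuntimeError(
                f"balancing did not converge in {max_iterations} iterations"
            )
    n = matrix.nbins
    weights = np.full(n, np.nan)
    weights[valid] = 1.0 / b
    balanced = np.zeros((n, n))
    balanced[np.ix_(valid, valid)] = sub / np.outer(b, b)
    return replace(matrix, balanced=balanced, weights=weights)


# ---------------------------------------------------------------------------
# Expected-by-distance and observed/expected
# ---------------------------------------------------------------------------

@dataclass
class ExpectedProfile:
    """Mean balanced value per bin-separation, per chromosome.

    ``per_chrom[c][d]`` is the mean over unmasked cis pairs at separation
    ``d`` bins (NaN where no unmasked pair exists; d=0 unused).
    ``trans_mean`` is the single genome-wide trans expectation.
    """

    per_chrom: dict[str, np.ndarray]
    trans_mean: float

    def pooled(self) -> np.ndarray:
        """Genome-wide profile: plain mean over chromosomes at each separation."""
        longest = max(len(v) for v in self.per_chrom.values())
        stack = np.full((len(self.per_chrom), longest), np.nan)
        for k, v in enumerate(self.per_chrom.values()):
            stack[k, : len(v)] = v
        with np.errstate(invalid="ignore"):
            return np.nanmean(stack, axis=0)


def expected_by_distance(matrix: ContactMatrix, use: str = "auto") -> ExpectedProfile:
    vals = matrix.values(use)
    per_chrom: dict[str, np.ndarray] = {}
    for chrom in matrix.genome.chromosomes:
        sl = matrix.genome.chrom_slice(chrom)
        sub = vals[sl, sl]
        m = matrix.mask[sl]
        n = sub.shape[0]
        prof = np.full(n, np.nan)
        for d in range(1, n):
            diag = np.diagonal(sub, d)
            ok = m[:-d] & m[d:]
            if ok.any():
                prof[d] = diag[ok].mean()
        per_chrom[chrom] = prof
    trans = ~matrix.cis_mask() & matrix.pair_valid()
    trans_mean = float(vals[trans].mean()) if trans.any() else float("nan")
    return ExpectedProfile(per_chrom, trans_mean)


def observed_over_expected(
    matrix: ContactMatrix, profile: ExpectedProfile | None = None, use: str = "auto"
) -> np.ndarray:
    """O/E matrix: balanced value over the distance expectation (cis only).

    Trans entries and pairs with undefined expectation are NaN; masked bins
    are NaN throughout.  Multiplying back by the profile reconstructs the
    balanced matrix exactly on defined pairs.
    """
    if profile is None:
        profile = expected_by_distance(matrix, use=use)
    vals = matrix.values(use)
    n = matrix.nbins
    oe = np.full((n, n), np.nan)
    for chrom in matrix.genome.chromosomes:
        sl = matrix.genome.chrom_slice(chrom)
        sub = vals[sl, sl]
        nc = sub.shape[0]
        idx = np.arange(nc)
        sep = np.abs(idx[:, None] - idx[None, :])
        prof = profile.per_chrom[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            exp = prof[sep]
            oe[sl, sl] = np.where(sep > 0, sub / exp, np.nan)
    invalid = ~matrix.pair_valid()
    oe[invalid] = np.nan
    return oe


# ---------------------------------------------------------------------------
# Coarsening and replicate correlation
# ---------------------------------------------------------------------------

def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum-pool to ``factor``× coarser bins; preserves total counts exactly.

    A coarse bin is masked only if all of its constituent bins were masked.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return matrix
    g = matrix.genome
    coarse = GenomeSpec(dict(g.chromosomes), g.resolution * factor)
    n2 = coarse.nbins
    # map fine bin -> coarse bin
    mapping = np.empty(g.nbins, dtype=np.int64)
    for chrom in g.chromosomes:
        fine = g.chrom_slice(chrom)
        co = coarse.chrom_slice(chrom)
        local = np.arange(fine.stop - fine.start) // factor
        mapping[fine] = co.start + local
    counts = np.zeros((n2, n2), dtype=matrix.counts.dtype)
    np.add.at(counts, (mapping[:, None], mapping[None, :]), matrix.counts)
    # pooled diagonal keeps within-coarse-bin pairs so totals are conserved;
    # it is excluded from statistics like every self-pair
    mask = np.zeros(n2, dtype=bool)
    np.logical_or.at(mask, mapping, matrix.mask)
    return ContactMatrix(coarse, counts, mask=mask)


def matrix_correlation(
    a: ContactMatrix,
    b: ContactMatrix,
    resolution: int | None = None,
    include_trans: bool = False,
) -> float:
    """Pearson correlation of two depth-normalized contact maps.

    Both matrices are optionally sum-pooled to ``resolution``, scaled to equal
    totals, and correlated over unmasked upper-triangle pairs (cis by
    default).
    """
    if a.genome.chromosomes != b.genome.chromosomes:
        raise ValueError("incompatible genomes")
    if resolution is not None:
        for m in (a, b):
            if resolution % m.genome.resolution != 0:
                raise ValueError("target resolution not a multiple of bin size")
        a = coarsen(a, resolution // a.genome.resolution)
        b = coarsen(b, resolution // b.genome.resolution)
    if a.genome.resolution != b.genome.resolution:
        raise ValueError("incompatible bin grids")
    va = a.counts / a.counts.sum()
    vb = b.counts / b.counts.sum()
    sel = np.triu(a.pair_valid() & b.pair_valid(), k=1)
    if not include_trans:
        sel &= a.cis_mask()
    x, y = va[sel], vb[sel]
    return float(np.corrcoef(x, y)[0, 1])
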