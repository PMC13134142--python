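"""Interval arithmetic for chromatin annotations.

Labeled BED-like interval sets (chromatin states, genomic features, LADs,
compartment calls), bp-overlap fold-enrichment matrices relative to the
genome-wide composition, aggregation of per-bin tracks over intervals, and
interval-size distributions.  All coordinates 0-based half-open; overlap is
measured in base pairs.  Set operations delegate to pyranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .genome import GenomeSpec

BED_COLUMNS = ["chrom", "start", "end", "label"]


@dataclass
class IntervalSet:
    """Labeled genomic intervals (chrom, start, end, label), sorted."""

    intervals: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        df = self.intervals
        if "label" not in df.columns:
            df = df.assign(label=".")
        df = df[BED_COLUMNS].copy()
        if (df["start"] >= df["end"]).any():
            raise ValueError("interval with start >= end")
        self.intervals = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].unique())

    def subset(self, label: str) -> pd.DataFrame:
        return self.intervals[self.intervals["label"] == label]

    def total_bp(self, label: str | None = None) -> int:
        df = self.intervals if label is None else self.subset(label)
        return int((df["end"] - df["start"]).sum())

    def to_ranges(self, label: str | None = None) -> pr.PyRanges:
        df = self.intervals if label is None else self.subset(label)
        return pr.PyRanges(
            df.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
                ["Chromosome", "Start", "End"]
            ]
        )


def read_bed(path: str, source: str = "") -> IntervalSet:
    """Read BED3 or BED4 (4th column = label)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return IntervalSet(df, source=source or str(path))


def write_bed(intervals: IntervalSet, path: str) -> None:
    intervals.intervals.to_csv(path, sep="\t", header=False, index=False)


def merge(intervals: IntervalSet) -> IntervalSet:
    """Merge overlapping and bookended intervals within each label."""
    out = []
    for label in intervals.labels:
        merged = intervals.to_ranges(label).merge(slack=0).df
        merged = merged.rename(
            columns={"Chromosome": "chrom", "Start": "start", "End": "end"}
        )
        merged["label"] = label
        out.append(merged[BED_COLUMNS])
    return IntervalSet(pd.concat(out, ignore_index=True), source=intervals.source)


def overlap_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total base pairs of overlap between two plain interval frames."""
    ga = pr.PyRanges(
        a.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
            ["Chromosome", "Start", "End"]
        ]
    )
    gb = pr.PyRanges(
        b.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
            ["Chromosome", "Start", "End"]
        ]
    )
    inter = ga.intersect(gb)
    if len(inter) == 0:
        return 0
    df = inter.df
    return int((df["End"] - df["Start"]).sum())


def coverage_fold_enrichment(
    states: IntervalSet, features: IntervalSet, genome: GenomeSpec
) -> pd.DataFrame:
    """States × features fold-enrichment relative to genome composition.

    ``enrichment(state, feature) = (overlap_bp / state_bp) / (feature_bp /
    genome_bp)``.  A feature covering the whole genome gives 1 for every
    state; a state disjoint from a feature gives 0.
    """
    genome_bp = sum(genome.chromosomes.values())
    rows = {}
    for s in states.labels:
        s_bp = states.total_bp(s)
        if s_bp == 0:
            raise ValueError(f"state {s!r} covers zero bp")
        row = {}
        for f in features.labels:
            f_bp = features.total_bp(f)
            if f_bp == 0:
                raise ValueError(f"feature {f!r} covers zero bp")
            ov = overlap_bp(states.subset(s), merge(IntervalSet(features.subset(f))).intervals)
            row[f] = (ov / s_bp) / (f_bp / genome_bp)
        rows[s] = row
    return pd.DataFrame(rows).T[features.labels]


def aggregate_track_over_intervals(
    track: pd.DataFrame, intervals: IntervalSet
) -> pd.DataFrame:
    """Overlap-bp-weighted mean of a per-bin track within each interval.

    ``track`` is bedGraph-like (chrom, start, end, value).  Intervals that
    overlap no defined bins get NaN.  Returns the interval frame with a
    ``mean`` column appended.
    """
    out = intervals.intervals.copy()
    means = np.full(len(out), np.nan)
    t = track.dropna(subset=["value"])
    for k, iv in enumerate(out.itertuples(index=False)):
        sel = t[t["chrom"] == iv.chrom]
        ov = np.minimum(sel["end"], iv.end) - np.maximum(sel["start"], iv.start)
        w = np.clip(ov, 0, None).to_numpy(float)
        if w.sum() > 0:
            means[k] = np.average(sel["value"].to_numpy(float), weights=w)
    out["mean"] = means
    return out


def interval_size_distribution(intervals: IntervalSet) -> pd.DataFrame:
    """Per-interval log10 size (bp) plus labels, for violin-style summaries."""
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    df = intervals.intervals.copy()
    df["size_bp"] = df["end"] - df["start"]
    df["log10_size"] = np.log10(df["size_bp"])
    return df


def rank_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (stat, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 defined values per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
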