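"""Radial positioning of chromatin bead-model ensembles.

Post-processing of simulated 3D nucleus models (one model = one nucleus, one
bead per genomic bin, Cartesian coordinates in arbitrary units): per-model
geometric center and bead distances, a nuclear-radius estimate from the
farthest 5% of beads, QC filtering, a three-way radial classification
(center / intermediate / peripheral at 20% and 80% of the radius), and
ensemble-averaged per-bin radial profiles with a LAD overlay.

Classification is performed per model against that model's own radius, so it
is invariant under rigid rotation and uniform scaling of any single model.
Diploid models may carry two beads per genomic bin; these are averaged within
a model before ensemble averaging.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CENTER_CUT = 0.20
PERIPHERAL_CUT = 0.80
RADIUS_TOP_FRACTION = 0.05
QC_MIN_BEADS = 20
QC_SD_MULTIPLIER = 3.0

BEAD_COLUMNS = ["chrom", "start", "end", "x", "y", "z", "valid"]


@dataclass
class BeadModel:
    """One simulated nucleus: beads with genomic assignment and coordinates."""

    model_id: str
    beads: pd.DataFrame  # columns BEAD_COLUMNS

    def __post_init__(self) -> None:
        missing = set(BEAD_COLUMNS) - set(self.beads.columns)
        if missing:
            raise ValueError(f"bead table missing columns {missing}")
        dup = self.beads.groupby(["chrom", "start"]).size()
        if (dup > 2).any():
            raise ValueError(
                f"model {self.model_id}: genomic bin assigned to >2 beads"
            )

    @property
    def n_valid(self) -> int:
        return int(self.beads["valid"].sum())

    def valid_coords(self) -> np.ndarray:
        return self.beads.loc[self.beads["valid"], ["x", "y", "z"]].to_numpy(float)


@dataclass
class BeadEnsemble:
    models: list[BeadModel]

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class RadialSummary:
    """Per-model geometry: center, distances, radius, classes for valid beads."""

    model_id: str
    center: np.ndarray
    distances: np.ndarray  # one per valid bead
    radius: float
    relative: np.ndarray
    classes: np.ndarray  # 'center' | 'intermediate' | 'peripheral'


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _finalize_beads(df: pd.DataFrame) -> pd.DataFrame:
    for c in ("x", "y", "z"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    coords = df[["x", "y", "z"]].to_numpy(float)
    df["valid"] = np.isfinite(coords).all(axis=1)
    return df[BEAD_COLUMNS]


def read_bead_models(paths: list[str | Path], dialect: str = "tsv") -> BeadEnsemble:
    """Read bead models from xyz-TSV or cmm-like XML marker files.

    TSV columns: chrom, start, end, x, y, z and optionally model; without a
    model column each file is one model named after the file stem.  Beads
    with missing or non-finite coordinates are kept but flagged invalid.
    """
    models: list[BeadModel] = []
    for path in paths:
        path = Path(path)
        if dialect == "tsv":
            df = pd.read_csv(path, sep="\t")
            if "model" in df.columns:
                for mid, grp in df.groupby("model", sort=False):
                    models.append(
                        BeadModel(str(mid), _finalize_beads(grp.copy().reset_index(drop=True)))
                    )
            else:
                models.append(BeadModel(path.stem, _finalize_beads(df.copy())))
        elif dialect == "cmm":
            root = ET.parse(path).getroot()
            sets = [root] if root.tag == "marker_set" else root.findall("marker_set")
            for ms in sets:
                rows = []
                for mk in ms.findall("marker"):
                    rows.append(
                        {
                            "chrom": mk.get("chrom", mk.get("chrID", "?")),
                            "start": int(mk.get("start", mk.get("beadID", 0))),
                            "end": int(mk.get("end", 0)),
                            "x": mk.get("x"),
                            "y": mk.get("y"),
                            "z": mk.get("z"),
                        }
                    )
                df = pd.DataFrame(rows)
                models.append(
                    BeadModel(ms.get("name", path.stem), _finalize_beads(df))
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return BeadEnsemble(models)


def write_bead_models(ensemble: BeadEnsemble, path: str | Path) -> None:
    """Write an ensemble as a single xyz-TSV with a model column."""
    frames = []
    for m in ensemble.models:
        df = m.beads.copy()
        df["model"] = m.model_id
        frames.append(df[["chrom", "start", "end", "x", "y", "z", "model"]])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def center_and_distances(model: BeadModel) -> tuple[np.ndarray, np.ndarray]:
    """Centroid of valid beads and each valid bead's Euclidean distance to it."""
    coords = model.valid_coords()
    if coords.shape[0] == 0:
        raise ValueError(f"model {model.model_id} has no valid beads")
    center = coords.mean(axis=0)
    return center, np.linalg.norm(coords - center, axis=1)


def nuclear_radius(
    distances: np.ndarray, top_fraction: float = RADIUS_TOP_FRACTION
) -> float:
    """Mean distance of the farthest ``ceil(top_fraction * n)`` beads.

    Ties at the cut are resolved by a stable descending sort, taking exactly
    ``ceil(top_fraction * n)`` values.
    """
    distances = np.asarray(distances, float)
    if distances.size == 0:
        raise ValueError("no distances")
    k = math.ceil(top_fraction * distances.size)
    order = np.argsort(-distances, kind="stable")
    return float(distances[order[:k]].mean())


def classify_beads(
    relative: np.ndarray,
    center_cut: float = CENTER_CUT,
    peripheral_cut: float = PERIPHERAL_CUT,
) -> np.ndarray:
    """Three-way class from relative radial distance.

    ``center`` strictly below ``center_cut``, ``peripheral`` strictly above
    ``peripheral_cut`` (values > 1 allowed and peripheral), boundary values
    assigned to ``intermediate``.
    """
    relative = np.asarray(relative, float)
    out = np.full(relative.shape, "intermediate", dtype=object)
    out[relative < center_cut] = "center"
    out[relative > peripheral_cut] = "peripheral"
    return out


def summarize_model(
    model: BeadModel,
    radius: float | None = None,
    center_cut: float = CENTER_CUT,
    peripheral_cut: float = PERIPHERAL_CUT,
) -> RadialSummary:
    """Center, distances, radius (own top-5% unless given) and classes."""
    center, dist = center_and_distances(model)
    r = nuclear_radius(dist) if radius is None else radius
    if r <= 0:
        raise ValueError("radius must be positive")
    rel = dist / r
    return RadialSummary(model.model_id, center, dist, r, rel, classify_beads(rel, center_cut, peripheral_cut))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    ensemble: BeadEnsemble,
    min_beads: int = QC_MIN_BEADS,
    sd_multiplier: float = QC_SD_MULTIPLIER,
) -> tuple[BeadEnsemble, list[tuple[str, str]]]:
    """Drop models with too few valid beads, then radius outliers.

    Returns the retained ensemble and an exclusion log of
    ``(model_id, reason)`` with reasons ``min_beads`` or ``radius_outlier``.
    """
    exclusions: list[tuple[str, str]] = []
    enough = []
    for m in ensemble.models:
        if m.n_valid < min_beads:
            exclusions.append((m.model_id, "min_beads"))
        else:
            enough.append(m)
    if not enough:
        raise ValueError("all models excluded by min_beads rule")
    radii = np.array([nuclear_radius(center_and_distances(m)[1]) for m in enough])
    mean, sd = radii.mean(), radii.std()
    kept = []
    for m, r in zip(enough, radii):
        if sd > 0 and abs(r - mean) > sd_multiplier * sd:
            exclusions.append((m.model_id, "radius_outlier"))
        else:
            kept.append(m)
    if not kept:
        raise ValueError("all models excluded")
    return BeadEnsemble(kept), exclusions


# ---------------------------------------------------------------------------
# Ensemble profile
# ---------------------------------------------------------------------------

def ensemble_radial_profile(
    ensemble: BeadEnsemble,
    lad_intervals: pd.DataFrame | None = None,
    center_cut: float = CENTER_CUT,
    peripheral_cut: float = PERIPHERAL_CUT,
    min_lad_overlap: float = 0.5,
) -> pd.DataFrame:
    """Per-genomic-bin radial profile averaged over models.

    For each model, duplicate (diploid) beads on a bin are averaged first;
    then per-bin relative distances and class indicators are averaged over
    all models containing that bin.  Output columns: chrom, start, end,
    mean_rel_dist, frac_center, frac_intermediate, frac_peripheral,
    n_models, is_lad.  ``lad_intervals`` is a BED-like frame (chrom, start,
    end); a bin is LAD-flagged when ≥ ``min_lad_overlap`` of it overlaps.
    """
    per_model: list[pd.DataFrame] = []
    for m in ensemble.models:
        s = summarize_model(m, center_cut=center_cut, peripheral_cut=peripheral_cut)
        beads = m.beads.loc[m.beads["valid"], ["chrom", "start", "end"]].copy()
        beads["rel"] = s.relative
        beads["is_center"] = (s.classes == "center").astype(float)
        beads["is_intermediate"] = (s.classes == "intermediate").astype(float)
        beads["is_peripheral"] = (s.classes == "peripheral").astype(float)
        per_model.append(beads.groupby(["chrom", "start", "end"], as_index=False).mean())
    allm = pd.concat(per_model, ignore_index=True)
    prof = allm.groupby(["chrom", "start", "end"], as_index=False).agg(
        mean_rel_dist=("rel", "mean"),
        frac_center=("is_center", "mean"),
        frac_intermediate=("is_intermediate", "mean"),
        frac_peripheral=("is_peripheral", "mean"),
        n_models=("rel", "size"),
    )
    prof = prof.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    prof["is_lad"] = False
    if lad_intervals is not None and len(lad_intervals):
        for _, lad in lad_intervals.iterrows():
            ov = (
                (prof["chrom"] == lad["chrom"])
                & (np.minimum(prof["end"], lad["end"]) - np.maximum(prof["start"], lad["start"])
                   >= min_lad_overlap * (prof["end"] - prof["start"]))
            )
            prof.loc[ov, "is_lad"] = True
    return prof
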