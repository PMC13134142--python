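"""Declarative multi-stage analysis pipeline.

A :class:`PipelineConfig` (flat YAML) names the ordered stages, either
per-stage matrix paths or a synthetic-data block, the analysis parameters
(all defaults mirror the 50-kb-resolution parameterization: DLR threshold
3 Mb, long-range cutoff 50 Mb, TAD bounds 150-500 kb with delta 0.01,
saddle Q), and a global seed.  :func:`run_pipeline` produces, per stage:
balanced matrix, distance curve, long-range fraction, PC1 track, saddle and
strength, DLR/ICF tracks with compartment stratification, insulation and
TADs, pileups; across stages: switch tables, domain-strength dynamics and
inter-TAD proportions; plus a manifest (config hash, seed, parameters,
outputs).  A rerun with the same config and seed reproduces byte-identical
TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as cp
from . import scaling as sc
from . import synthetic as syn
from . import tads as td
from .genome import GenomeSpec
from .matrix import (
    ContactMatrix,
    balance_matrix,
    expected_by_distance,
    mask_low_coverage,
    observed_over_expected,
    read_matrix,
)

log = logging.getLogger("hicarch")

FLOAT_FORMAT = "%.10g"

DEFAULT_PARAMS = {
    "min_fraction_of_median": 0.1,
    "dlr_threshold_bp": sc.DLR_THRESHOLD_BP,
    "long_range_cutoff_bp": sc.LONG_RANGE_CUTOFF_BP,
    "n_log_bins": 20,
    "insulation_windows_bp": list(td.INSULATION_WINDOWS_BP),
    "tad_min_bp": td.TAD_MIN_SIZE_BP,
    "tad_max_bp": td.TAD_MAX_SIZE_BP,
    "boundary_delta": td.BOUNDARY_DELTA,
    "pileup_flank_bp": td.PILEUP_FLANK_BP,
    "saddle_quantiles": cp.SADDLE_QUANTILES,
    "saddle_corner_fraction": cp.SADDLE_CORNER_FRACTION,
    "inter_tad_window_edges_bp": [0, 20_000_000, 50_000_000, 80_000_000],
}


class PipelineError(Exception):
    """Configuration or stage failure; carries a named stage context."""


@dataclass
class PipelineConfig:
    stages: list[str]
    genome: GenomeSpec
    output_dir: Path
    seed: int = 0
    matrices: dict[str, str] = field(default_factory=dict)  # stage -> path
    synthetic: dict = field(default_factory=dict)
    ensemble: dict | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stages:
            raise PipelineError("configuration error: empty stage list")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        if self.matrices:
            for stage in self.stages:
                if stage not in self.matrices:
                    raise PipelineError(f"no matrix path for stage {stage!r}")
                if not Path(self.matrices[stage]).exists():
                    raise PipelineError(f"missing matrix file {self.matrices[stage]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        g = raw.get("genome", {})
        genome = GenomeSpec(dict(g.get("chromosomes", {})), int(g.get("resolution", 0)))
        return cls(
            stages=list(raw.get("stages", [])),
            genome=genome,
            output_dir=Path(raw.get("output_dir", "hicarch_out")),
            seed=int(raw.get("seed", 0)),
            matrices=dict(raw.get("matrices", {})),
            synthetic=dict(raw.get("synthetic", {})),
            ensemble=raw.get("ensemble"),
            params=dict(raw.get("params", {})),
        )

    def canonical(self) -> str:
        payload = {
            "stages": self.stages,
            "genome": {
                "chromosomes": self.genome.chromosomes,
                "resolution": self.genome.resolution,
            },
            "seed": self.seed,
            "matrices": self.matrices,
            "synthetic": self.synthetic,
            "ensemble": self.ensemble,
            "params": self.params,
        }
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


def _per_stage_value(block: dict, key: str, k: int, default):
    """Synthetic-block values may be scalars or per-stage lists."""
    v = block.get(key, default)
    if isinstance(v, (list, tuple)):
        return v[k]
    return v


def _stage_specs(config: PipelineConfig) -> list[syn.StageSpec]:
    blk = config.synthetic
    specs = []
    for k, label in enumerate(config.stages):
        specs.append(
            syn.StageSpec(
                label=label,
                alpha=float(_per_stage_value(blk, "alpha", k, 1.0)),
                strength=float(_per_stage_value(blk, "strength", k, 0.3)),
                tads=[tuple(t) for t in blk.get("tads", [])],
                tad_boost=float(_per_stage_value(blk, "tad_boost", k, 1.0)),
                longrange_boost=float(_per_stage_value(blk, "longrange_boost", k, 1.0)),
                longrange_cutoff_bp=int(blk.get("longrange_cutoff_bp", 50_000_000)),
                trans_level=float(_per_stage_value(blk, "trans_level", k, 0.0)),
                depth=float(_per_stage_value(blk, "depth", k, 5e5)),
                seed=config.seed * 1000 + k,
            )
        )
    return specs


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _track_frame(genome: GenomeSpec, values: np.ndarray, name: str) -> pd.DataFrame:
    bins = genome.bins()[["chrom", "start", "end"]].copy()
    bins[name] = values
    return bins


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full per-stage and cross-stage analysis; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = config.genome
    params = config.params
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": params,
        "stages": config.stages,
        "outputs": [],
        "warnings": [],
    }

    def emit(df: pd.DataFrame, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_tsv(df, path)
        manifest["outputs"].append(rel)

    # ---- load or simulate per-stage matrices --------------------------------
    profiles: list[np.ndarray] | None = None
    truth = None
    if config.matrices:
        mats = [read_matrix(config.matrices[s]) for s in config.stages]
    else:
        specs = _stage_specs(config)
        mats, profiles, truth = syn.simulate_stage_series(
            genome,
            specs,
            switch_fraction=float(config.synthetic.get("switch_fraction", 0.0)),
            a_to_b_fraction=float(config.synthetic.get("a_to_b_fraction", 0.5)),
            seed=config.seed,
        )
        if truth is not None and len(truth):
            emit(truth, "switch_truth.tsv")

    # ---- per-stage analyses --------------------------------------------------
    oe_per_stage: list[np.ndarray] = []
    labels_per_stage: list[np.ndarray] = []
    stage_summary_rows = []
    reference_tads = None
    insulation_per_stage = []
    for k, (stage, mat) in enumerate(zip(config.stages, mats)):
        try:
            mat = mask_low_coverage(mat, params["min_fraction_of_median"])
            masked_frac = 1.0 - mat.mask.mean()
            if masked_frac > 0.2:
                msg = f"stage {stage}: {masked_frac:.1%} of bins masked"
                log.warning(msg)
                manifest["warnings"].append(msg)
            mat = balance_matrix(mat)
            profile = expected_by_distance(mat)
            oe = observed_over_expected(mat, profile)
            oe_per_stage.append(oe)

            curve = sc.contact_frequency_vs_distance(
                mat, n_log_bins=params["n_log_bins"], normalize=True
            )
            emit(curve.to_frame(), f"{stage}/distance_curve.tsv")
            lrf = sc.long_range_fraction(mat, params["long_range_cutoff_bp"])

            # compartments: per-chromosome PC1, oriented on the reference track
            pc1 = np.full(genome.nbins, np.nan)
            for chrom in genome.chromosomes:
                sl = genome.chrom_slice(chrom)
                res = cp.compute_pc1(oe[sl, sl], valid=mat.mask[sl])
                reference = (
                    profiles[k][sl].astype(float)
                    if profiles is not None
                    else mat.counts[sl].sum(axis=1).astype(float)
                )
                oriented, _ = cp.orient_pc1(res.values, reference)
                pc1[sl] = oriented
            labels = cp.labels_from_pc1(pc1)
            labels_per_stage.append(labels)
            emit(_track_frame(genome, pc1, "pc1"), f"{stage}/pc1.tsv")

            sad = cp.saddle(
                oe, pc1, params["saddle_quantiles"], params["saddle_corner_fraction"]
            )
            emit(
                pd.DataFrame(sad.matrix),
                f"{stage}/saddle.tsv",
            )
            ratios = cp.compartment_contact_ratio(mat, labels, scope="cis", profile=profile)

            dlr_track = sc.dlr(mat, params["dlr_threshold_bp"])
            emit(_track_frame(genome, dlr_track, "dlr"), f"{stage}/dlr.tsv")
            dlr_summary, dlr_p = sc.stratify_track(dlr_track, labels, compare=("A", "B"))
            emit(dlr_summary, f"{stage}/dlr_by_compartment.tsv")
            icf_track = sc.icf(mat)
            emit(_track_frame(genome, icf_track, "icf"), f"{stage}/icf.tsv")

            ins = td.insulation_score(mat, tuple(params["insulation_windows_bp"]))
            insulation_per_stage.append(ins)
            emit(_track_frame(genome, ins.values, "insulation"), f"{stage}/insulation.tsv")
            tadset = td.find_boundaries(
                ins,
                genome,
                delta=params["boundary_delta"],
                min_size_bp=params["tad_min_bp"],
                max_size_bp=params["tad_max_bp"],
            )
            emit(tadset.boundaries, f"{stage}/boundaries.tsv")
            emit(tadset.domains, f"{stage}/domains.tsv")
            if reference_tads is None and len(tadset.domains):
                reference_tads = tadset.domains
            if len(tadset.domains):
                pile, skipped = td.tad_pileup(
                    oe, genome, tadset.domains, flank_bp=params["pileup_flank_bp"]
                )
                emit(pd.DataFrame(pile), f"{stage}/tad_pileup.tsv")
                for s in skipped:
                    log.info("stage %s: pileup skipped edge domain %s", stage, s)

            stage_summary_rows.append(
                {
                    "stage": stage,
                    "long_range_fraction": lrf,
                    "compartment_strength": sad.strength,
                    "log2_AA": ratios["AA"],
                    "log2_BB": ratios["BB"],
                    "log2_AB": ratios["AB"],
                    "dlr_A_vs_B_pvalue": dlr_p,
                    "mean_icf": float(np.nanmean(icf_track)),
                    "n_boundaries": len(tadset.boundaries),
                    "n_domains": len(tadset.domains),
                }
            )
        except PipelineError:
            raise
        except Exception as exc:  # named, logged stage failure
            manifest["failed_stage"] = stage
            log.error("stage %s failed: %s", stage, exc)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    emit(pd.DataFrame(stage_summary_rows), "stage_summary.tsv")

    # ---- cross-stage analyses ------------------------------------------------
    if len(mats) > 1:
        switch_rows = []
        for k in range(len(mats) - 1):
            table = cp.classify_switching(labels_per_stage[k], labels_per_stage[k + 1])
            frame = table.to_frame()
            frame.insert(0, "transition", f"{config.stages[k]}->{config.stages[k + 1]}")
            switch_rows.append(frame)
        emit(pd.concat(switch_rows, ignore_index=True), "switch_tables.tsv")

        if reference_tads is not None and len(reference_tads):
            dyn = td.strength_dynamics(oe_per_stage, genome, reference_tads, config.stages)
            emit(dyn, "strength_dynamics.tsv")
            prop_rows = []
            for stage, mat in zip(config.stages, mats):
                props = td.inter_tad_distance_proportions(
                    mat, reference_tads, tuple(params["inter_tad_window_edges_bp"])
                )
                props.insert(0, "stage", stage)
                prop_rows.append(props)
            emit(pd.concat(prop_rows, ignore_index=True), "inter_tad_proportions.tsv")

    # ---- radial ensembles ----------------------------------------------------
    if config.ensemble is not None:
        from . import radial as rd

        blk = dict(config.ensemble)
        lad_flags = None
        espec = syn.EnsembleSpec(
            n_models=int(blk.get("n_models", 50)),
            genome=genome,
            radius=float(blk.get("radius", 1.0)),
            lad_flags=lad_flags,
            peripheral_bias=float(blk.get("peripheral_bias", 0.0)),
            degraded_fraction=float(blk.get("degraded_fraction", 0.0)),
            seed=config.seed + 9000,
        )
        ensemble = syn.simulate_bead_ensemble(espec)
        filtered, exclusions = rd.qc_filter(ensemble)
        prof = rd.ensemble_radial_profile(filtered)
        emit(prof, "radial_profile.tsv")
        with open(out / "radial_exclusions.log", "w") as fh:
            for mid, reason in exclusions:
                fh.write(f"{mid}\t{reason}\n")
        manifest["outputs"].append("radial_exclusions.log")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
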