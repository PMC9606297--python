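"""File formats, configuration and the pipeline driver.

Canonical dialect: tab-separated tables with a commented header line
(``#chrom\tstart\t...``); genomic intervals are 0-based half-open
throughout (BED-compatible).  Readers validate coordinates and segment
non-overlap and report malformed rows with line numbers; every pipeline
run emits a JSON manifest (version, config hash, input checksums, seeds)
so deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clonality import AllelicSegmentProfile

logger = logging.getLogger(__name__)

SEGMENT_FIELDS = ["chrom", "start", "end", "raw_minor", "raw_major",
                  "ploidy", "patient", "region"]


# -- segments -----------------------------------------------------------------

def write_segments(profiles, path) -> None:
    """Write region profiles to the SEG-like TSV dialect."""
    rows = []
    for p in profiles:
        for _, s in p.segments.iterrows():
            rows.append([s["chrom"], int(s["start"]), int(s["end"]),
                         s["raw_minor"], s["raw_major"], p.ploidy,
                         p.patient_id, p.region_id])
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SEGMENT_FIELDS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_segments(path, one_based: bool = False) -> list:
    """Read region profiles from the SEG-like TSV dialect.

    With ``one_based=True`` input coordinates are 1-based inclusive and
    converted (start - 1).  Rows with raw_minor > raw_major are
    normalized by swapping, with a warning; malformed rows raise with
    their line number; overlapping segments within a region are a hard
    error naming the overlap.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing commented header line")
        header = first[1:].strip().split("\t")
        if header != SEGMENT_FIELDS:
            raise ValueError(f"{path}: header {header} != {SEGMENT_FIELDS}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(SEGMENT_FIELDS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(SEGMENT_FIELDS)} fields, "
                                 f"got {len(parts)}")
            try:
                rows.append({
                    "chrom": parts[0], "start": int(parts[1]),
                    "end": int(parts[2]), "raw_minor": float(parts[3]),
                    "raw_major": float(parts[4]), "ploidy": float(parts[5]),
                    "patient": parts[6], "region": parts[7]})
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows)
    if one_based:
        df["start"] -= 1
    swap = df["raw_minor"] > df["raw_major"]
    if swap.any():
        logger.warning("%s: %d rows had raw_minor > raw_major; swapped",
                       path, int(swap.sum()))
        lo = df.loc[swap, ["raw_minor", "raw_major"]].min(axis=1)
        hi = df.loc[swap, ["raw_minor", "raw_major"]].max(axis=1)
        df.loc[swap, "raw_minor"] = lo
        df.loc[swap, "raw_major"] = hi
    profiles = []
    for (patient, region), grp in df.groupby(["patient", "region"],
                                             sort=True):
        ploidies = grp["ploidy"].unique()
        if len(ploidies) != 1:
            raise ValueError(f"{path}: region {patient}/{region} has "
                             f"multiple ploidies {ploidies}")
        seg = (grp[["chrom", "start", "end", "raw_minor", "raw_major"]]
               .sort_values(["chrom", "start"]).reset_index(drop=True))
        for chrom, cgrp in seg.groupby("chrom"):
            starts = cgrp["start"].values
            ends = cgrp["end"].values
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if len(bad):
                i = bad[0]
                raise ValueError(
                    f"{path}: overlapping segments in {patient}/{region} "
                    f"on {chrom}: [{starts[i]},{ends[i]}) overlaps "
                    f"[{starts[i + 1]},{ends[i + 1]})")
        profiles.append(AllelicSegmentProfile(
            patient_id=patient, region_id=region,
            segments=seg, ploidy=float(ploidies[0])))
    return profiles


# -- BED / bedGraph / tables --------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}"
                                        for i in range(3, df.shape[1])]
    df.columns = cols
    if df.shape[1] >= 4:
        df = df.rename(columns={"col3": "name"})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end"] + list(extra_cols)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: pd.DataFrame, value_col: str, path) -> None:
    """Write one frequency-track category as bedGraph (NaN rows skipped)."""
    sub = track.dropna(subset=[value_col])
    sub[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def read_plates(path) -> pd.DataFrame:
    """Read a plate CSV (sample, drug, dose, replicate, signal,
    is_control)."""
    df = pd.read_csv(path)
    required = {"sample", "drug", "dose", "replicate", "signal",
                "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing plate columns {sorted(missing)}")
    df["is_control"] = df["is_control"].astype(bool)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_sets(path) -> dict:
    """Read gene sets from GMT (name, description, members...) or a
    two-column TSV (set name, gene); format detected per line width.

    Returns {set name: list of member genes}.
    """
    sets: dict = {}
    two_col_pairs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if len(parts) >= 3:  # GMT: name, description, members...
                sets[parts[0]] = [g for g in parts[2:] if g]
            else:
                two_col_pairs.append((parts[0], parts[1]))
    for name, gene in two_col_pairs:
        sets.setdefault(name, []).append(gene)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


# -- configuration and manifest -----------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (all stages toggleable).

    Threshold overrides ship in one block so sensitivity sweeps are
    single-field changes; every random stage carries an explicit seed.
    """

    out_dir: str = "scna_out"
    # stage toggles
    run_simulate: bool = True
    run_clonality: bool = True
    run_cnprofile: bool = True
    run_dose_response: bool = True
    run_associate: bool = True
    # input paths (used when the simulate stage is off)
    segments_path: str | None = None
    mask_path: str | None = None
    bins_path: str | None = None
    plates_path: str | None = None
    # per-stage seeds
    seed_simulate: int = 0
    seed_associate: int = 1
    # thresholds (documented defaults; see clonality / copy_number /
    # dose_response modules)
    loh_minor_threshold: float = 0.25
    outlier_weight_threshold: float = 0.4
    ic50_level: float = 0.5
    prevalence_threshold: float = 0.05
    # simulator scale
    n_patients: int = 10
    n_plates: int = 12
    cn_noise_sd: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.loh_minor_threshold <= 1:
            raise ValueError("loh_minor_threshold must lie in [0, 1]")
        if not 0 < self.outlier_weight_threshold < 1:
            raise ValueError("outlier_weight_threshold must lie in (0, 1)")
        if not 0 < self.ic50_level < 1:
            raise ValueError("ic50_level must lie in (0, 1)")
        if not 0 <= self.prevalence_threshold <= 1:
            raise ValueError("prevalence_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(config: PipelineConfig, input_paths: dict) -> dict:
    cfg = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    return {
        "tool_version": __version__,
        "config": cfg,
        "config_hash": cfg_hash,
        "input_checksums": {k: _sha256(v) for k, v in input_paths.items()
                            if v and Path(v).exists()},
        "seeds": {"simulate": config.seed_simulate,
                  "associate": config.seed_associate},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages end to end, writing outputs and a run
    manifest into ``config.out_dir``.

    Stage order: simulate -> clonality -> copy-number profile ->
    dose-response -> association.  A downstream stage whose input is
    missing fails before any computation with the dependency named.
    Row counts and exclusions are logged at INFO.
    """
    from . import association, clonality, copy_number, dose_response
    from . import synthetic

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # dependency check up front
    if config.run_clonality and not config.run_simulate \
            and not config.segments_path:
        raise ValueError("clonality stage needs segments: enable the "
                         "simulate stage or set segments_path")
    if config.run_dose_response and not config.run_simulate \
            and not config.plates_path:
        raise ValueError("dose-response stage needs plates: enable the "
                         "simulate stage or set plates_path")

    outputs: dict = {}
    profiles = truth = mask = None
    plates_df = None

    if config.run_simulate:
        sim_cfg = synthetic.CohortSimConfig(
            n_patients=config.n_patients,
            cn_noise_sd=config.cn_noise_sd,
            seed=config.seed_simulate)
        profiles, truth, mask = synthetic.simulate_multiregion_cohort(sim_cfg)
        write_segments(profiles, out / "segments.tsv")
        truth.to_csv(out / "truth_events.tsv", sep="\t", index=False)
        logger.info("simulated %d regions / %d patients, %d planted events",
                    len(profiles), config.n_patients, len(truth))
        plate_rows = []
        for i in range(config.n_plates):
            pl, _ = synthetic.simulate_plate(
                synthetic.PlateSimConfig(seed=config.seed_simulate + 1 + i),
                sample_id=f"S{i % 4}", drug_id=f"D{i // 4}")
            plate_rows.append(pl)
        plates_df = pd.concat(plate_rows, ignore_index=True)
        plates_df.to_csv(out / "plates.csv", index=False)
        outputs["segments"] = str(out / "segments.tsv")
        outputs["plates"] = str(out / "plates.csv")
    else:
        if config.segments_path:
            profiles = read_segments(config.segments_path)
        if config.mask_path:
            mask = read_bed(config.mask_path)
        if config.plates_path:
            plates_df = read_plates(config.plates_path)

    if config.run_clonality:
        by_patient: dict = {}
        for p in profiles:
            by_patient.setdefault(p.patient_id, []).append(p)
        all_calls = []
        for patient, pp in by_patient.items():
            consensus = clonality.build_consensus(
                pp, mask=mask,
                loh_minor_threshold=config.loh_minor_threshold)
            all_calls.extend(clonality.classify_clonality(consensus))
        calls = clonality.calls_to_frame(all_calls)
        calls.to_csv(out / "clonality_calls.tsv", sep="\t", index=False)
        logger.info("clonality: %d calls across %d patients",
                    len(calls), len(by_patient))
        outputs["clonality_calls"] = str(out / "clonality_calls.tsv")

    if config.run_cnprofile:
        geno, _ = synthetic.simulate_cohort_genotypes(
            synthetic.GenotypeSimConfig(seed=config.seed_simulate + 101))
        profile = copy_number.cohort_frequency_profile(geno)
        profile.to_csv(out / "cn_frequency_profile.tsv", sep="\t")
        outputs["cn_frequency_profile"] = str(
            out / "cn_frequency_profile.tsv")

    auc_table = None
    if config.run_dose_response:
        if plates_df is None:
            raise ValueError("dose-response stage has no plate input")
        results = []
        for (sample, drug), grp in plates_df.groupby(["sample", "drug"]):
            plate = dose_response.DosePlate(sample_id=sample, drug_id=drug,
                                            wells=grp.reset_index(drop=True))
            res = dose_response.analyze_plate(
                plate, weight_threshold=config.outlier_weight_threshold,
                ic50_level=config.ic50_level)
            results.append({
                "sample": sample, "drug": drug, "auc": res.auc,
                "ic50": res.ic50, "ic50_censored": res.ic50_censored,
                "n_outliers": res.diagnostics.get("n_outliers", 0)})
        res_df = pd.DataFrame(results)
        res_df.to_csv(out / "dose_response.tsv", sep="\t", index=False)
        logger.info("dose-response: %d plates analysed", len(res_df))
        outputs["dose_response"] = str(out / "dose_response.tsv")
        auc_table = res_df.pivot(index="sample", columns="drug",
                                 values="auc")

    if config.run_associate:
        nullsim = association.null_simulation_study(
            reps=200, seed=config.seed_associate)
        write_json({"mean_max_abs_r": nullsim["mean_max_abs_r"],
                    "mean_min_abs_r": nullsim["mean_min_abs_r"],
                    "reps": nullsim["reps"]},
                   out / "null_simulation.json")
        outputs["null_simulation"] = str(out / "null_simulation.json")

    manifest = make_manifest(config, {
        "segments": config.segments_path,
        "plates": config.plates_path,
        "mask": config.mask_path})
    write_json(manifest, out / "manifest.json")
    outputs["manifest"] = str(out / "manifest.json")
    return outputs
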