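"""Clonal/subclonal classification of somatic copy-number alterations (SCNAs)
from multi-region allele-specific copy-number profiles.

A tumour is sampled at several anatomically distinct regions; each region
carries an allele-specific copy-number segmentation (raw minor/major copy
number per segment) plus a sample ploidy.  Gains and losses are called per
segment relative to ploidy on the log2 scale:

    raw_total_CN = log2((raw_minor + raw_major) / ploidy)

    gain  iff raw_total_CN > log2(2.5 / 2)
    loss  iff raw_total_CN < log2(1.5 / 2)

An event is *clonal* when every region of the patient carries it, and
*subclonal* when at least one but not all regions do.  A loss is also
carried by a region when the segment shows loss of heterozygosity (LOH,
minor allele copy number near zero), even if total copy number is neutral
relative to ploidy.

All genomic intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# -- thresholds ---------------------------------------------------------------

#: gain iff raw_total_CN strictly above log2(2.5/2)
GAIN_THRESHOLD: float = math.log2(2.5 / 2.0)
#: loss iff raw_total_CN strictly below log2(1.5/2)
LOSS_THRESHOLD: float = math.log2(1.5 / 2.0)
#: a segment carries LOH when its raw minor copy number falls below this
LOH_MINOR_THRESHOLD: float = 0.25

#: sentinel for a homozygous-null segment (total raw copy number of zero);
#: mathematically log2(0) = -inf, always classified as loss.
HOMOZYGOUS_NULL: float = float("-inf")

SEGMENT_COLUMNS = ["chrom", "start", "end", "raw_minor", "raw_major"]


@dataclass
class AllelicSegmentProfile:
    """One tumour region's allele-specific copy-number segmentation.

    ``segments`` is a DataFrame with columns chrom, start, end, raw_minor,
    raw_major; intervals are 0-based half-open, sorted and non-overlapping
    within each chromosome; raw_minor <= raw_major by convention.
    """

    patient_id: str
    region_id: str
    segments: pd.DataFrame
    ploidy: float

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValueError(f"segments missing columns: {missing}")
        for chrom, grp in seg.groupby("chrom", sort=False):
            s = grp.sort_values("start")
            if (s["end"] <= s["start"]).any():
                raise ValueError(f"empty/negative segment on {chrom}")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(
                    f"overlapping segments on {chrom} in region "
                    f"{self.region_id} of patient {self.patient_id}"
                )

    @property
    def chromosomes(self) -> set:
        return set(self.segments["chrom"].unique())


@dataclass
class ConsensusProfile:
    """Intersection segmentation of all regions of one patient.

    ``segments`` holds chrom/start/end of the consensus pieces (mask
    removed); ``raw_total_cn`` and ``loh`` are (n_segments x n_regions)
    arrays aligned with ``region_ids``.
    """

    patient_id: str
    region_ids: list
    segments: pd.DataFrame
    raw_total_cn: np.ndarray
    loh: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class ClonalityCall:
    """Gain/loss clonality labels for one consensus locus of one patient."""

    patient_id: str
    chrom: str
    start: int
    end: int
    gain_label: str  # clonal | subclonal | none
    loss_label: str  # clonal | subclonal | none


# -- per-segment state --------------------------------------------------------

def raw_total_cn(raw_minor, raw_major, ploidy):
    """Ploidy-normalised non-allele-specific copy number, per segment.

    Returns log2((raw_minor + raw_major) / ploidy).  A total raw copy
    number of zero yields :data:`HOMOZYGOUS_NULL` (-inf) rather than
    raising; it is treated as loss downstream.  Accepts scalars or arrays.
    """
    minor = np.asarray(raw_minor, dtype=float)
    major = np.asarray(raw_major, dtype=float)
    if np.any(minor < 0) or np.any(major < 0):
        raise ValueError("raw copy numbers must be non-negative")
    if np.any(np.asarray(ploidy) <= 0):
        raise ValueError("ploidy must be > 0")
    total = minor + major
    with np.errstate(divide="ignore"):
        out = np.log2(total / ploidy)
    if out.ndim == 0:
        return float(out)
    return out


def classify_state(value, gain_threshold: float = GAIN_THRESHOLD,
                   loss_threshold: float = LOSS_THRESHOLD) -> str:
    """Classify one raw_total_CN value as 'gain', 'loss' or 'neutral'.

    Inequalities are strict: a value exactly at a threshold is neutral.
    The homozygous-null sentinel (-inf) classifies as loss.
    """
    if np.isnan(value):
        raise ValueError("cannot classify NaN copy number")
    if value > gain_threshold:
        return "gain"
    if value < loss_threshold:
        return "loss"
    return "neutral"


def classify_states(values: np.ndarray,
                    gain_threshold: float = GAIN_THRESHOLD,
                    loss_threshold: float = LOSS_THRESHOLD) -> np.ndarray:
    """Vectorised :func:`classify_state`; returns an object array of labels."""
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, "neutral", dtype=object)
    out[values > gain_threshold] = "gain"
    out[values < loss_threshold] = "loss"
    return out


# -- consensus construction ---------------------------------------------------

def _subtract_intervals(start: int, end: int,
                        masked: Sequence[tuple]) -> list:
    """Pieces of [start, end) not covered by the (sorted) masked intervals."""
    pieces = []
    cursor = start
    for ms, me in masked:
        if me <= cursor or ms >= end:
            continue
        if ms > cursor:
            pieces.append((cursor, min(ms, end)))
        cursor = max(cursor, me)
        if cursor >= end:
            break
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def build_consensus(profiles: Sequence[AllelicSegmentProfile],
                    mask: pd.DataFrame | None = None,
                    loh_minor_threshold: float = LOH_MINOR_THRESHOLD,
                    ) -> ConsensusProfile:
    """Build the patient consensus profile over the union of breakpoints.

    Consensus breakpoints are the union of every region's breakpoints
    (intersection segmentation), so each region contributes exactly one
    raw_total_CN value and one LOH flag per consensus segment.  Intervals
    overlapping ``mask`` (BED-like DataFrame: chrom, start, end) are
    removed.  Per-region values are carried, never averaged: clonality
    needs each region's own state.

    Consensus pieces not covered by some region carry NaN for that region
    and are dropped (all regions must cover a locus for clonality to be
    well defined there).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one region profile")
    patient_ids = {p.patient_id for p in profiles}
    if len(patient_ids) != 1:
        raise ValueError(f"profiles span multiple patients: {sorted(patient_ids)}")
    chrom_sets = [p.chromosomes for p in profiles]
    if any(cs != chrom_sets[0] for cs in chrom_sets):
        detail = {p.region_id: sorted(p.chromosomes) for p in profiles}
        raise ValueError(f"regions have disjoint chromosome sets: {detail}")

    mask_by_chrom: dict = {}
    if mask is not None and len(mask):
        for chrom, grp in mask.groupby("chrom", sort=False):
            iv = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
            mask_by_chrom[chrom] = iv

    region_ids = [p.region_id for p in profiles]
    rows, cn_rows, loh_rows = [], [], []
    for chrom in sorted(chrom_sets[0]):
        breakpoints = set()
        for p in profiles:
            seg = p.segments[p.segments["chrom"] == chrom]
            breakpoints.update(seg["start"].astype(int))
            breakpoints.update(seg["end"].astype(int))
        bps = sorted(breakpoints)
        masked = mask_by_chrom.get(chrom, [])
        for lo, hi in zip(bps[:-1], bps[1:]):
            for start, end in _subtract_intervals(lo, hi, masked):
                cn_vals = np.full(len(profiles), np.nan)
                loh_vals = np.zeros(len(profiles), dtype=bool)
                for k, p in enumerate(profiles):
                    seg = p.segments
                    hit = seg[(seg["chrom"] == chrom)
                              & (seg["start"] <= start)
                              & (seg["end"] >= end)]
                    if len(hit):
                        row = hit.iloc[0]
                        cn_vals[k] = raw_total_cn(
                            row["raw_minor"], row["raw_major"], p.ploidy)
                        loh_vals[k] = row["raw_minor"] < loh_minor_threshold
                if np.isnan(cn_vals).any():
                    continue  # locus not covered by every region
                rows.append((chrom, start, end))
                cn_rows.append(cn_vals)
                loh_rows.append(loh_vals)

    segments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    cn = np.array(cn_rows) if cn_rows else np.empty((0, len(profiles)))
    loh = (np.array(loh_rows) if loh_rows
           else np.empty((0, len(profiles)), dtype=bool))
    return ConsensusProfile(
        patient_id=profiles[0].patient_id,
        region_ids=region_ids,
        segments=segments,
        raw_total_cn=cn,
        loh=loh,
    )


# -- clonality ----------------------------------------------------------------

def _label(n_with_event: int, n_regions: int) -> str:
    if n_with_event == 0:
        return "none"
    if n_with_event == n_regions:
        return "clonal"
    return "subclonal"


def classify_clonality(consensus: ConsensusProfile,
                       gain_threshold: float = GAIN_THRESHOLD,
                       loss_threshold: float = LOSS_THRESHOLD,
                       ) -> list[ClonalityCall]:
    """Per consensus segment, call gain and loss clonality independently.

    A region "has gain" at a segment iff its raw_total_CN classifies as
    gain; it "has loss" iff it classifies as loss *or* the LOH flag is
    set.  Clonal = event in all regions, subclonal = in some but not all.
    For a single-region patient subclonality is undefined; labels are
    restricted to {clonal, none} and a warning is logged.
    """
    n = consensus.n_regions
    if n == 1:
        logger.warning(
            "patient %s has a single region: subclonality is undefined, "
            "labels restricted to {clonal, none}", consensus.patient_id)
    calls = []
    for i, row in consensus.segments.iterrows():
        states = classify_states(consensus.raw_total_cn[i],
                                 gain_threshold, loss_threshold)
        gains = int(np.sum(states == "gain"))
        losses = int(np.sum((states == "loss") | consensus.loh[i]))
        calls.append(ClonalityCall(
            patient_id=consensus.patient_id,
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            gain_label=_label(gains, n),
            loss_label=_label(losses, n),
        ))
    return calls


def calls_to_frame(calls: Iterable[ClonalityCall]) -> pd.DataFrame:
    """Tabulate clonality calls (one row per patient x consensus segment)."""
    return pd.DataFrame(
        [(c.patient_id, c.chrom, c.start, c.end, c.gain_label, c.loss_label)
         for c in calls],
        columns=["patient", "chrom", "start", "end",
                 "gain_label", "loss_label"])


TRACK_CATEGORIES = ["clonal_gain", "subclonal_gain",
                    "clonal_loss", "subclonal_loss",
                    "total_gain", "total_loss"]


def clonality_frequency_track(calls: pd.DataFrame,
                              bins: pd.DataFrame) -> pd.DataFrame:
    """Cohort frequency of clonal/subclonal gains and losses per genomic bin.

    ``calls``: DataFrame as from :func:`calls_to_frame`, possibly many
    patients.  ``bins``: BED-like DataFrame (chrom, start, end).  Returns
    one row per bin with the percentage of *covered* patients carrying
    each category, plus combined ``total_gain``/``total_loss`` tracks
    (clonal + subclonal).  A patient covers a bin when at least one of its
    consensus segments overlaps it; a bin covered by no patient (e.g.
    fully masked) is reported as missing (NaN), not 0.
    """
    if bins is None or len(bins) == 0:
        raise ValueError("empty bin set")
    patients = calls["patient"].unique()
    out_rows = []
    for _, b in bins.iterrows():
        chrom, bstart, bend = b["chrom"], int(b["start"]), int(b["end"])
        over = calls[(calls["chrom"] == chrom)
                     & (calls["start"] < bend)
                     & (calls["end"] > bstart)]
        counts = dict.fromkeys(TRACK_CATEGORIES, 0)
        n_covered = 0
        for pat in patients:
            sub = over[over["patient"] == pat]
            if len(sub) == 0:
                continue
            n_covered += 1
            g = set(sub["gain_label"])
            l = set(sub["loss_label"])
            if "clonal" in g:
                counts["clonal_gain"] += 1
            elif "subclonal" in g:
                counts["subclonal_gain"] += 1
            if "clonal" in l:
                counts["clonal_loss"] += 1
            elif "subclonal" in l:
                counts["subclonal_loss"] += 1
            if g & {"clonal", "subclonal"}:
                counts["total_gain"] += 1
            if l & {"clonal", "subclonal"}:
                counts["total_loss"] += 1
        row = {"chrom": chrom, "start": bstart, "end": bend,
               "n_covered": n_covered}
        for cat in TRACK_CATEGORIES:
            row[cat] = (100.0 * counts[cat] / n_covered
                        if n_covered else np.nan)
        out_rows.append(row)
    return pd.DataFrame(out_rows)
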