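"""Gene-level adjusted copy number, categorical state calling and
GISTIC-style cohort frequency profiles.

Adjusted (absolute) copy number — ACN — is on the integer copy scale after
ploidy adjustment.  The continuous scale is discretised into five states
with boundaries at 0.5 / 1.5 / 2.5 / 4.5:

    [0, 0.5)    homozygous_loss
    [0.5, 1.5)  heterozygous_loss
    [1.5, 2.5)  neutral
    [2.5, 4.5)  gain            (integers 3 and 4)
    [4.5, inf)  amplification   (integers >= 5)

so the integer definitions "gain = 3 or 4 copies, amplification >= 5" are
reproduced exactly.  The 3-level view collapses integers to {2, 3, 4+}.
Relative copy number (RCN) is on the log2-ratio scale; where conversion is
needed, ACN = ploidy * 2**RCN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ["homozygous_loss", "heterozygous_loss", "neutral",
              "gain", "amplification"]

#: category boundaries on the continuous ACN scale (left-closed bins)
ACN_BOUNDARIES = (0.5, 1.5, 2.5, 4.5)


@dataclass
class GeneCNMatrix:
    """Genes x samples absolute (ploidy-adjusted) copy numbers.

    ``acn`` is a DataFrame indexed by gene, columns = samples, values
    non-negative reals (NaN = missing).  ``gene_intervals`` optionally
    carries the genomic interval per gene (chrom, start, end).  ``rcn``
    optionally holds relative copy numbers on the log2-ratio scale.
    """

    acn: pd.DataFrame
    gene_intervals: pd.DataFrame | None = None
    rcn: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.acn.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.acn.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (self.acn.values < 0).any():
            raise ValueError("ACN values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.acn.index

    @property
    def samples(self) -> pd.Index:
        return self.acn.columns

    def categories(self) -> pd.DataFrame:
        """Five-state categorical view (derived, never stored)."""
        vals = categorize_acn_array(self.acn.values.ravel())
        return pd.DataFrame(vals.reshape(self.acn.shape),
                            index=self.acn.index, columns=self.acn.columns)

    def levels3(self) -> pd.DataFrame:
        """3-level view on rounded ACN: '2' (<=2), '3', '4+'."""
        rounded = self.acn.round().values
        out = np.empty(rounded.shape, dtype=object)
        finite = np.isfinite(rounded)
        out[finite] = [acn_to_levels(v) for v in rounded[finite]]
        out[~finite] = None
        return pd.DataFrame(out, index=self.acn.index,
                            columns=self.acn.columns)


def rcn_to_acn(rcn, ploidy: float = 2.0):
    """Convert log2-ratio relative copy number to the adjusted scale."""
    return ploidy * np.power(2.0, np.asarray(rcn, dtype=float))


# -- gene-level summarisation -------------------------------------------------

def gene_acn_from_segments(segments: pd.DataFrame,
                           gene_interval: tuple) -> float:
    """Gene-level ACN from a segment table (chrom, start, end, acn).

    The gene takes the ACN of the segment with the *largest overlap*;
    ties are broken toward the higher copy number so focal amplifications
    split across a boundary are not missed.  No overlapping segment
    returns NaN (logged).
    """
    chrom, gstart, gend = gene_interval
    seg = segments[(segments["chrom"] == chrom)
                   & (segments["start"] < gend)
                   & (segments["end"] > gstart)]
    if len(seg) == 0:
        logger.warning("no segment overlaps gene interval %s", gene_interval)
        return float("nan")
    overlap = (np.minimum(seg["end"].values, gend)
               - np.maximum(seg["start"].values, gstart))
    acn = seg["acn"].values.astype(float)
    best = overlap == overlap.max()
    return float(acn[best].max())


# -- categorisation -----------------------------------------------------------

def categorize_acn(acn: float) -> str:
    """Five-state category of one continuous ACN value (see module doc)."""
    if acn < 0 or not np.isfinite(acn):
        raise ValueError(f"ACN must be finite and non-negative, got {acn}")
    b = ACN_BOUNDARIES
    if acn < b[0]:
        return "homozygous_loss"
    if acn < b[1]:
        return "heterozygous_loss"
    if acn < b[2]:
        return "neutral"
    if acn < b[3]:
        return "gain"
    return "amplification"


def categorize_acn_array(values) -> np.ndarray:
    """Vectorised :func:`categorize_acn`; NaN maps to None (missing)."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if (values[finite] < 0).any():
        raise ValueError("ACN values must be non-negative")
    idx = np.digitize(values, ACN_BOUNDARIES)  # boundaries -> right bin
    out = np.empty(values.shape, dtype=object)
    for i in range(5):
        out[(idx == i) & finite] = CATEGORIES[i]
    out[~finite] = None
    return out


def acn_to_levels(acn) -> str:
    """Collapse an integer ACN to the 3-level scale: '2', '3' or '4+'."""
    acn = int(acn)
    if acn < 0:
        raise ValueError("ACN must be non-negative")
    if acn <= 2:
        return "2"
    if acn == 3:
        return "3"
    return "4+"


# -- cohort frequency profiles ------------------------------------------------

def cohort_frequency_profile(matrix: GeneCNMatrix,
                             subset=None) -> pd.DataFrame:
    """Per-gene percentage of samples in each copy-number category.

    ``subset``: optional list of sample ids or boolean predicate over
    sample ids selecting the cohort of interest.  Missing values are
    excluded from denominators.  Returns one row per gene with the five
    category percentages plus combined ``gain_or_amp`` and ``any_loss``
    tracks and the non-missing count ``n``.
    """
    acn = matrix.acn
    if subset is not None:
        if callable(subset):
            cols = [s for s in acn.columns if subset(s)]
        else:
            cols = list(subset)
        if len(cols) == 0:
            raise ValueError(f"empty sample subset (predicate: {subset!r})")
        acn = acn[cols]
    rows = []
    for gene, vals in acn.iterrows():
        cats = categorize_acn_array(vals.values)
        non_missing = np.array([c is not None for c in cats])
        n = int(non_missing.sum())
        row = {"gene": gene, "n": n}
        for cat in CATEGORIES:
            row[cat] = (100.0 * np.sum(cats == cat) / n) if n else np.nan
        if n:
            row["gain_or_amp"] = row["gain"] + row["amplification"]
            row["any_loss"] = row["homozygous_loss"] + row["heterozygous_loss"]
        else:
            row["gain_or_amp"] = row["any_loss"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def marker_groups(matrix: GeneCNMatrix, marker_gene: str,
                  comparison: str = "neutral") -> tuple[list, list]:
    """Split samples by a marker gene's copy-number status.

    Returns (altered, reference) sample lists: *altered* = samples where
    the marker is gained or amplified; *reference* = neutral samples only
    (default) or, with ``comparison='non_altered'``, every sample that is
    not gained/amplified (pooling losses).
    """
    if marker_gene not in matrix.genes:
        raise ValueError(f"marker gene {marker_gene!r} not in matrix")
    cats = categorize_acn_array(matrix.acn.loc[marker_gene].values)
    samples = np.asarray(matrix.samples)
    altered = samples[np.isin(cats, ["gain", "amplification"])].tolist()
    if comparison == "neutral":
        ref = samples[cats == "neutral"].tolist()
    elif comparison == "non_altered":
        keep = [c is not None and c not in ("gain", "amplification")
                for c in cats]
        ref = samples[np.array(keep)].tolist()
    else:
        raise ValueError(f"unknown comparison group {comparison!r}")
    return altered, ref


def group_frequency_difference(matrix: GeneCNMatrix, marker_gene: str,
                               pathway_labels: pd.Series | dict,
                               comparison: str = "neutral") -> pd.DataFrame:
    """Per-gene SCNA frequency difference between marker-altered and
    marker-reference samples, annotated by pathway membership.

    For each gene the difference ``freq(marker gain/amp) - freq(reference)``
    is computed for 'amplification or gain' (``diff_gain_amp``) and, on a
    reverse scale (negated, so that more loss in the marker-altered group
    is negative), for loss (``diff_loss``).  ``pathway_labels`` maps gene
    -> bool (True = PI3K/RAS pathway membership).
    """
    altered, ref = marker_groups(matrix, marker_gene, comparison)
    if len(altered) == 0 or len(ref) == 0:
        raise ValueError(
            f"marker {marker_gene!r} yields an empty group "
            f"(altered n={len(altered)}, reference n={len(ref)})")
    prof_alt = cohort_frequency_profile(matrix, subset=altered)
    prof_ref = cohort_frequency_profile(matrix, subset=ref)
    labels = pd.Series(pathway_labels)
    out = pd.DataFrame(index=matrix.genes)
    out["diff_gain_amp"] = prof_alt["gain_or_amp"] - prof_ref["gain_or_amp"]
    out["diff_loss"] = -(prof_alt["any_loss"] - prof_ref["any_loss"])
    membership = labels.reindex(matrix.genes)
    out["pi3k_ras"] = membership.where(membership.notna(),
                                       False).astype(bool)
    return out.drop(index=marker_gene, errors="ignore")
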