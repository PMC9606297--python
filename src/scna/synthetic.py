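"""Synthetic-data generators with known ground truth for every pipeline
stage: multi-region copy-number cohorts with planted clonal/subclonal
events, viability plates from log-logistic truth curves, cohort genotypes
with a planted MYC-PI3K/RAS co-occurrence effect, and expression matrices
linearly coupled to copy number.

All generators take a single integer seed, draw from one
``numpy.random.Generator`` in a fixed documented order, and return
machine-readable ground truth alongside the data; truth values are
computed from the generating model (closed form or quadrature), never
from the noisy output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .clonality import AllelicSegmentProfile
from .copy_number import GeneCNMatrix
from .dose_response import loglogistic5

DEFAULT_GENOME = [(f"chr{i}", 100_000_000) for i in range(1, 6)]

#: default PI3K/RAS pathway gene panel with pathway membership flags
DEFAULT_GENE_PANEL = {
    "PIK3CA": True, "AKT1": True, "AKT2": True, "AKT3": True,
    "KRAS": True, "PTEN": True, "NF1": True, "RPTOR": True,
    "GAB2": True, "IGF1R": True,
    "CCNE1": False, "TERT": False, "RB1": False, "TP53": False,
    "CDKN2A": False, "CCND1": False, "MCL1": False, "ERBB2": False,
    "BRCA1": False, "BRCA2": False,
}


def _sample_from_spec(rng: np.random.Generator, spec: dict, size=None):
    """Draw from a small declarative sampler spec.

    Supported: {'type': 'constant', 'value': v},
    {'type': 'choice', 'values': [...], 'probs': [...] (optional)},
    {'type': 'loguniform', 'low': a, 'high': b},
    {'type': 'uniform', 'low': a, 'high': b}.
    """
    kind = spec["type"]
    if kind == "constant":
        v = spec["value"]
        return v if size is None else np.full(size, v)
    if kind == "choice":
        return rng.choice(np.asarray(spec["values"], dtype=float),
                          size=size, p=spec.get("probs"))
    if kind == "loguniform":
        lo, hi = math.log(spec["low"]), math.log(spec["high"])
        return np.exp(rng.uniform(lo, hi, size=size))
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=size)
    raise ValueError(f"unknown sampler spec type {kind!r}")


# =====================================================================
# multi-region cohort
# =====================================================================

@dataclass
class CohortSimConfig:
    """Study conditions for the multi-region copy-number simulator.

    Defaults emulate the multi-region whole-genome cohort the clonality
    analysis assumes: ~30 patients with a handful of regions each
    (median 4), a genome of a few 100-Mb chromosomes, base ploidy 2,
    several clonal and subclonal events per patient with multi-megabase
    lengths, and mild additive noise on the raw allele copy numbers.
    """

    n_patients: int = 30
    regions_per_patient: tuple = (2, 6)   # inclusive range, or an int
    genome: list = field(default_factory=lambda: list(DEFAULT_GENOME))
    ploidy_distribution: dict = field(
        default_factory=lambda: {"type": "constant", "value": 2.0})
    clonal_event_rate: float = 4.0
    subclonal_event_rate: float = 4.0
    event_length_distribution: dict = field(
        default_factory=lambda: {"type": "loguniform",
                                 "low": 5_000_000, "high": 30_000_000})
    cn_noise_sd: float = 0.1
    mask_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if isinstance(self.regions_per_patient, int):
            self.regions_per_patient = (self.regions_per_patient,
                                        self.regions_per_patient)
        lo, hi = self.regions_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("invalid regions_per_patient range")
        if not self.genome or any(length <= 0 for _, length in self.genome):
            raise ValueError("genome must list chromosomes of positive length")
        if self.clonal_event_rate < 0 or self.subclonal_event_rate < 0:
            raise ValueError("event rates must be >= 0")
        if self.subclonal_event_rate > 0 and hi == 1:
            raise ValueError(
                "subclonal events need >=2 regions per patient "
                "(a strict nonempty subset cannot exist with 1 region)")
        if self.cn_noise_sd < 0:
            raise ValueError("cn_noise_sd must be >= 0")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must lie in [0, 1)")


def _place_events(rng, genome, n_events, length_spec, occupied):
    """Place non-overlapping events on the genome by rejection sampling."""
    chroms, lengths = zip(*genome)
    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()
    placed = []
    for _ in range(n_events):
        for _attempt in range(200):
            ci = rng.choice(len(chroms), p=weights)
            chrom, clen = chroms[ci], lengths[ci]
            ev_len = int(min(_sample_from_spec(rng, length_spec), clen))
            start = int(rng.integers(0, clen - ev_len + 1))
            end = start + ev_len
            if all(not (chrom == oc and start < oe and end > os)
                   for oc, os, oe in occupied):
                occupied.append((chrom, start, end))
                placed.append((chrom, start, end))
                break
        # event silently dropped if no free slot after 200 attempts
    return placed


def simulate_multiregion_cohort(config: CohortSimConfig
                                ) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Generate per-region allele-specific segment profiles with planted
    clonal and subclonal gains and losses.

    Per patient: base allele state is (ploidy/2, ploidy/2) genome-wide; a
    planted gain adds one copy to the major allele in the carrying
    regions; a planted loss zeroes the minor allele (an LOH loss).
    Clonal events are present in every region, subclonal events in a
    uniformly chosen strict nonempty proper subset.  Raw copy numbers are
    the true allele values plus additive Gaussian noise truncated at 0;
    segments tile each chromosome exactly (no gaps, no overlaps).

    Returns ``(profiles, truth, mask)``: the region profiles, a truth
    table (patient, chrom, start, end, direction, clonality, regions)
    and a BED-like mask table drawn to cover ``mask_fraction`` of the
    genome while avoiding planted events.
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[AllelicSegmentProfile] = []
    truth_rows = []
    lo, hi = config.regions_per_patient
    chrom_lengths = dict(config.genome)

    # cohort-level mask, drawn first so event placement can avoid it
    mask_rows = []
    occupied_global: list = []
    if config.mask_fraction > 0:
        total = sum(chrom_lengths.values())
        target = config.mask_fraction * total
        masked = 0
        while masked < target:
            chrom, clen = config.genome[rng.integers(len(config.genome))]
            mlen = int(min(clen * 0.02, target - masked) + 1)
            start = int(rng.integers(0, clen - mlen + 1))
            mask_rows.append({"chrom": chrom, "start": start,
                              "end": start + mlen})
            occupied_global.append((chrom, start, start + mlen))
            masked += mlen
    mask = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])

    for p in range(config.n_patients):
        patient = f"P{p:03d}"
        n_regions = int(rng.integers(lo, hi + 1))
        region_ids = [f"R{r}" for r in range(n_regions)]
        ploidy = float(_sample_from_spec(rng, config.ploidy_distribution))
        n_clonal = int(rng.poisson(config.clonal_event_rate))
        n_sub = (int(rng.poisson(config.subclonal_event_rate))
                 if n_regions > 1 else 0)
        occupied = list(occupied_global)
        clonal_events = _place_events(rng, config.genome, n_clonal,
                                      config.event_length_distribution,
                                      occupied)
        sub_events = _place_events(rng, config.genome, n_sub,
                                   config.event_length_distribution,
                                   occupied)
        events = []
        for chrom, start, end in clonal_events:
            direction = "gain" if rng.random() < 0.5 else "loss"
            events.append((chrom, start, end, direction, "clonal",
                           list(range(n_regions))))
        for chrom, start, end in sub_events:
            direction = "gain" if rng.random() < 0.5 else "loss"
            k = int(rng.integers(1, n_regions))  # strict proper subset
            carriers = sorted(rng.choice(n_regions, size=k, replace=False))
            events.append((chrom, start, end, direction, "subclonal",
                           [int(c) for c in carriers]))
        for chrom, start, end, direction, clonality, carriers in events:
            truth_rows.append({
                "patient": patient, "chrom": chrom,
                "start": start, "end": end, "direction": direction,
                "clonality": clonality,
                "regions": ",".join(region_ids[c] for c in carriers)})

        # segment tiling: union of event breakpoints per chromosome
        for r in range(n_regions):
            seg_rows = []
            for chrom, clen in config.genome:
                bps = {0, clen}
                for ec, es, ee, *_ in events:
                    if ec == chrom:
                        bps.update((es, ee))
                bps = sorted(bps)
                for s, e in zip(bps[:-1], bps[1:]):
                    minor = ploidy / 2.0
                    major = ploidy / 2.0
                    for ec, es, ee, direction, _clon, carriers in events:
                        if ec == chrom and es <= s and ee >= e \
                                and r in carriers:
                            if direction == "gain":
                                major += 1.0
                            else:
                                minor = 0.0
                    if config.cn_noise_sd > 0:
                        minor = max(0.0, minor + rng.normal(
                            0, config.cn_noise_sd))
                        major = max(0.0, major + rng.normal(
                            0, config.cn_noise_sd))
                    lo_cn, hi_cn = sorted((minor, major))
                    seg_rows.append((chrom, s, e, lo_cn, hi_cn))
            segments = pd.DataFrame(
                seg_rows,
                columns=["chrom", "start", "end", "raw_minor", "raw_major"])
            profiles.append(AllelicSegmentProfile(
                patient_id=patient, region_id=region_ids[r],
                segments=segments, ploidy=ploidy))

    truth = pd.DataFrame(
        truth_rows, columns=["patient", "chrom", "start", "end",
                             "direction", "clonality", "regions"])
    return profiles, truth, mask


# =====================================================================
# viability plates
# =====================================================================

def halflog_doses(n: int = 8, lowest: float = 1e-9) -> tuple:
    """An n-point half-log (sqrt(10)-fold) dilution series in molar."""
    return tuple(lowest * 10 ** (i / 2) for i in range(n))


@dataclass
class PlateSimConfig:
    """Study conditions for the viability-plate simulator: an 8-point
    half-log dose series, technical triplicates, multiplicative
    log-normal noise and optional spike-in outliers."""

    doses: tuple = field(default_factory=halflog_doses)
    replicates_per_dose: int = 3
    n_control_wells: int = 16
    # (slope, lower, upper, log_inflection_dose, asymmetry) of the truth
    # 5PL on the natural-log dose axis
    truth_model: tuple = (1.5, 0.1, 1.0, math.log(1e-7), 1.0)
    noise_cv: float = 0.05
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    control_signal: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if len(doses) < 4:
            raise ValueError("need >=4 distinct doses for the spline fit")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        b, c, d, e, f = self.truth_model
        if c > d:
            raise ValueError("truth lower asymptote exceeds upper")
        if f <= 0:
            raise ValueError("asymmetry must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")


def plate_truth(config: PlateSimConfig) -> dict:
    """Analytic ground truth of a plate configuration.

    Truth AUC is the dose-range-normalized integral on the log-dose axis
    of the truth curve standardized by its upper asymptote (the control
    level), by adaptive quadrature; truth IC50 is the root of the
    standardized curve at 0.5 (None when there is no crossing in range).
    """
    b, c, d, e, f = config.truth_model
    log_doses = np.log(np.asarray(config.doses, dtype=float))
    a_dom, b_dom = log_doses[0], log_doses[-1]

    def std_curve(x):
        return loglogistic5(x, b, c, d, e, f) / d

    integral, _ = integrate.quad(std_curve, a_dom, b_dom, limit=200)
    truth_auc = integral / (b_dom - a_dom)
    grid = np.linspace(a_dom, b_dom, 1024)
    vals = std_curve(grid) - 0.5
    if vals[0] <= 0:
        truth_ic50 = float(np.exp(a_dom))
    else:
        below = np.nonzero(vals <= 0)[0]
        if len(below) == 0:
            truth_ic50 = None
        else:
            i = below[0]
            truth_ic50 = float(np.exp(optimize.brentq(
                lambda z: std_curve(z) - 0.5, grid[i - 1], grid[i])))
    return {"auc": float(truth_auc), "ic50": truth_ic50,
            "model": tuple(config.truth_model)}


def simulate_plate(config: PlateSimConfig,
                   sample_id: str = "S0", drug_id: str = "D0"
                   ) -> tuple[pd.DataFrame, dict]:
    """Simulate one plate (dose, replicate, signal, is_control) plus
    analytic truth.

    Control wells are drawn at the truth upper asymptote; test-well
    signal follows the truth 5PL at each dose.  Multiplicative noise is
    ``1 + cv * N(0,1)`` truncated at 0.01; outliers multiply a uniformly
    chosen subset of test wells by ``outlier_magnitude`` (their row
    indices are recorded in the truth dict).
    """
    rng = np.random.default_rng(config.seed)
    b, c, d, e, f = config.truth_model
    s0 = config.control_signal
    rows = []
    for _ in range(config.n_control_wells):
        noise = max(0.01, 1 + config.noise_cv * rng.standard_normal())
        rows.append({"sample": sample_id, "drug": drug_id, "dose": 0.0,
                     "replicate": 0, "signal": s0 * d * noise,
                     "is_control": True})
    for dose in config.doses:
        mean_signal = s0 * loglogistic5(math.log(dose), b, c, d, e, f)
        for rep in range(config.replicates_per_dose):
            noise = max(0.01, 1 + config.noise_cv * rng.standard_normal())
            rows.append({"sample": sample_id, "drug": drug_id,
                         "dose": float(dose), "replicate": rep,
                         "signal": float(mean_signal * noise),
                         "is_control": False})
    plate = pd.DataFrame(rows)
    test_idx = plate.index[~plate["is_control"]].to_numpy()
    n_out = int(round(config.outlier_rate * len(test_idx)))
    outlier_idx = (sorted(rng.choice(test_idx, size=n_out, replace=False))
                   if n_out else [])
    for i in outlier_idx:
        plate.loc[i, "signal"] *= config.outlier_magnitude
    truth = plate_truth(config)
    truth["outlier_indices"] = [int(i) for i in outlier_idx]
    return plate, truth


# =====================================================================
# cohort genotypes
# =====================================================================

@dataclass
class GenotypeSimConfig:
    """Study conditions for the cohort-genotype simulator with a planted
    MYC-PI3K/RAS co-occurrence effect."""

    n_samples: int = 200
    gene_panel: dict = field(
        default_factory=lambda: dict(DEFAULT_GENE_PANEL))
    myc_amp_fraction: float = 0.3
    co_occurrence_log_odds: float = 1.0
    baseline_scna_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_panel:
            raise ValueError("gene panel must be non-empty")
        if not 0 <= self.myc_amp_fraction <= 1:
            raise ValueError("myc_amp_fraction must lie in [0, 1]")
        if not np.isfinite(self.co_occurrence_log_odds):
            raise ValueError("co_occurrence_log_odds must be finite")
        if not 0 < self.baseline_scna_rate < 1:
            raise ValueError("baseline_scna_rate must lie in (0, 1)")


def simulate_cohort_genotypes(config: GenotypeSimConfig
                              ) -> tuple[GeneCNMatrix, dict]:
    """Generate a gene x sample ACN matrix with planted co-occurrence.

    MYC is amplified (ACN 5) in ``myc_amp_fraction`` of samples, neutral
    (ACN 2) otherwise.  Each panel gene is altered (ACN 5) with
    probability sigmoid(logit(baseline) + log_odds * MYC-amplified) for
    PI3K/RAS genes and at the baseline rate for others; unaltered genes
    are neutral.  Returns the matrix and the truth parameters.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    myc_amp = rng.random(config.n_samples) < config.myc_amp_fraction
    logit_base = math.log(config.baseline_scna_rate
                          / (1 - config.baseline_scna_rate))
    data = {"MYC": np.where(myc_amp, 5.0, 2.0)}
    for gene, in_pathway in config.gene_panel.items():
        if gene == "MYC":
            continue
        logit = logit_base + (config.co_occurrence_log_odds * myc_amp
                              if in_pathway else 0.0)
        prob = 1.0 / (1.0 + np.exp(-logit))
        altered = rng.random(config.n_samples) < prob
        data[gene] = np.where(altered, 5.0, 2.0)
    acn = pd.DataFrame(data, index=samples).T
    matrix = GeneCNMatrix(acn=acn)
    truth = {
        "co_occurrence_log_odds": config.co_occurrence_log_odds,
        "myc_amp_samples": [s for s, m in zip(samples, myc_amp) if m],
        "pathway_genes": [g for g, v in config.gene_panel.items() if v],
        "baseline_scna_rate": config.baseline_scna_rate,
    }
    return matrix, truth


# =====================================================================
# expression / copy-number / methylation coupling
# =====================================================================

def simulate_expression_cn(n_genes_per_group: dict, effect_sizes: dict,
                           n_samples: int = 100, noise_sd: float = 1.0,
                           methylation_coupling: float = 0.3,
                           seed: int = 0) -> dict:
    """Expression linearly coupled to copy number with group-specific
    effect sizes, plus a methylation matrix negatively coupled to the
    CN-expression coupling.

    ``n_genes_per_group`` and ``effect_sizes`` map group label (e.g.
    'driver', 'cancer_nonprevalent', ...) to gene count and slope.  Per
    gene: CN drawn uniformly from {1..6} per sample; expression =
    effect * CN + N(0, noise_sd); methylation beta values are centred at
    0.5 - methylation_coupling * effect (clipped to [0.01, 0.99]) plus
    noise.  Returns dict with expr, cn, methylation (genes x samples
    DataFrames) and the per-gene group labels.
    """
    if set(n_genes_per_group) != set(effect_sizes):
        raise ValueError("group and effect-size labels must match")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    genes, groups, effects = [], [], []
    for group, n in n_genes_per_group.items():
        for i in range(n):
            genes.append(f"{group}_g{i:03d}")
            groups.append(group)
            effects.append(effect_sizes[group])
    effects = np.asarray(effects, dtype=float)
    cn = rng.integers(1, 7, size=(len(genes), n_samples)).astype(float)
    expr = (effects[:, None] * cn
            + noise_sd * rng.standard_normal(cn.shape))
    meth_centre = np.clip(0.5 - methylation_coupling * effects, 0.01, 0.99)
    meth = np.clip(meth_centre[:, None]
                   + 0.05 * rng.standard_normal(cn.shape), 0.0, 1.0)
    return {
        "expr": pd.DataFrame(expr, index=genes, columns=samples),
        "cn": pd.DataFrame(cn, index=genes, columns=samples),
        "methylation": pd.DataFrame(meth, index=genes, columns=samples),
        "group": pd.Series(groups, index=genes),
        "effect_size": pd.Series(effects, index=genes),
        "seed": seed,
    }
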