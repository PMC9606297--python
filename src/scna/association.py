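"""Resampling tests, trend tests, enrichment scores and calibration
utilities linking gene copy number to drug response and expression.

Conventions shared by every resampling procedure here:

* one explicit integer seed per call; identical seed => identical result;
* Monte-Carlo p-values follow the add-one rule p = (b + 1) / (B + 1)
  where b counts resamples at least as extreme as the observed statistic
  (ties count as extreme — conservative);
* exact enumerations (small permutation / Jonckheere-Terpstra instances)
  report the exact tail proportion without the add-one correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: hard ceiling for explicit exact enumeration
EXACT_ENUMERATION_LIMIT = 1_000_000
#: 'auto' switches from exact to permutation above this many arrangements
AUTO_EXACT_LIMIT = 50_000


@dataclass
class ResamplingTestResult:
    """Outcome of one resampling / rank / enrichment test."""

    method: str
    statistic: float
    p_value: float
    n_resamples: int | None = None
    seed: int | None = None
    sidedness: str = "one-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of (0,1]: {self.p_value}")


@dataclass
class AssociationSpec:
    """A pre-specified gene copy-number / drug-response association with
    its expected direction ('sensitizing': higher CN -> lower AUC;
    'resistant': higher CN -> higher AUC)."""

    gene: str
    drug: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("sensitizing", "resistant"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class GeneSet:
    name: str
    members: frozenset

    def __init__(self, name: str, members) -> None:
        self.name = name
        self.members = frozenset(members)
        if not self.members:
            raise ValueError("gene set must be non-empty")


# -- permutation test on mean differences -------------------------------------

def permutation_mean_difference_test(
        in_set: np.ndarray, out_set: np.ndarray,
        R: int = 10_000, seed: int = 0,
        alternative: str = "greater") -> ResamplingTestResult:
    """One-sided permutation test of mean(in_set) - mean(out_set).

    Group labels are permuted R times; p follows the add-one rule with
    ties counted as at least as extreme.  ``alternative='greater'`` tests
    for a positive mean difference, ``'less'`` for a negative one.
    """
    a = np.asarray(in_set, dtype=float)
    b = np.asarray(out_set, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if R < 1:
        raise ValueError("R must be >= 1")
    sign = {"greater": 1.0, "less": -1.0}[alternative]
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    rng = np.random.default_rng(seed)
    b_count = 0
    tol = 1e-12 * max(1.0, abs(observed))
    total = pooled.sum()
    # mean difference is a function of the group-A sum alone
    for start in range(0, R, 2000):
        batch = min(2000, R - start)
        order = np.argsort(rng.random((batch, n)), axis=1)[:, :n_a]
        sum_a = pooled[order].sum(axis=1)
        stat = sum_a / n_a - (total - sum_a) / (n - n_a)
        b_count += int(np.sum(sign * stat >= sign * observed - tol))
    return ResamplingTestResult(
        method="permutation_mean_difference",
        statistic=observed, p_value=(b_count + 1) / (R + 1),
        n_resamples=R, seed=seed, sidedness=f"one-sided ({alternative})")


def permutation_cooccurrence_test(
        matrix, marker_gene: str, pathway_labels,
        R: int = 10_000, seed: int = 0,
        comparison: str = "neutral") -> ResamplingTestResult:
    """Patient-level permutation test for pathway-specific co-occurrence.

    The observed statistic is the mean per-gene gain/amp frequency
    difference (marker-altered vs marker-reference samples) over PI3K/RAS
    genes minus the mean over other genes.  The null permutes *samples*
    (the marker gene's copy-number row), re-deriving every per-gene
    difference per resample — the patient-resampling variant of
    :func:`permutation_mean_difference_test`.
    """
    from .copy_number import categorize_acn_array, marker_groups

    altered, ref = marker_groups(matrix, marker_gene, comparison)
    if len(altered) == 0 or len(ref) == 0:
        raise ValueError(
            f"marker {marker_gene!r} yields an empty group "
            f"(altered n={len(altered)}, reference n={len(ref)})")
    genes = [g for g in matrix.genes if g != marker_gene]
    labels = pd.Series(pathway_labels).reindex(genes)
    in_path = labels.where(labels.notna(), False).values.astype(bool)
    if in_path.all() or not in_path.any():
        raise ValueError("pathway labels give an empty gene group")
    acn = matrix.acn.loc[genes]
    cats = categorize_acn_array(acn.values.ravel()).reshape(acn.shape)
    gain_amp = np.isin(cats, ["gain", "amplification"]).astype(float)
    samples = list(matrix.samples)
    alt_mask = np.isin(samples, altered)
    ref_mask = np.isin(samples, ref)

    def _stat(a_mask, r_mask) -> float:
        diff = 100.0 * (gain_amp[:, a_mask].mean(axis=1)
                        - gain_amp[:, r_mask].mean(axis=1))
        return float(diff[in_path].mean() - diff[~in_path].mean())

    observed = _stat(alt_mask, ref_mask)
    rng = np.random.default_rng(seed)
    b_count = 0
    tol = 1e-12 * max(1.0, abs(observed))
    for _ in range(R):
        perm = rng.permutation(len(samples))
        if _stat(alt_mask[perm], ref_mask[perm]) >= observed - tol:
            b_count += 1
    return ResamplingTestResult(
        method="permutation_cooccurrence",
        statistic=observed, p_value=(b_count + 1) / (R + 1),
        n_resamples=R, seed=seed)


# -- bootstrap test on correlation sets ---------------------------------------

def bootstrap_correlation_set_test(
        within: np.ndarray, cross: np.ndarray,
        B: int = 25_000, seed: int = 0) -> ResamplingTestResult:
    """Non-parametric bootstrap test that within-pathway correlations
    exceed cross-pathway correlations on average.

    Each set is resampled with replacement B times; the one-sided p is
    the (add-one) bootstrap tail probability that the resampled mean
    difference is <= 0 (percentile-style tail).
    """
    w = np.asarray(within, dtype=float)
    c = np.asarray(cross, dtype=float)
    if len(w) == 0 or len(c) == 0:
        raise ValueError("both correlation sets must be non-empty")
    if len(w) == 1 or len(c) == 1:
        logger.warning("a correlation set has size 1: degenerate resampling")
    observed = float(w.mean() - c.mean())
    rng = np.random.default_rng(seed)
    wb = rng.choice(w, size=(B, len(w)), replace=True).mean(axis=1)
    cb = rng.choice(c, size=(B, len(c)), replace=True).mean(axis=1)
    b_count = int(np.sum(wb - cb <= 0))
    return ResamplingTestResult(
        method="bootstrap_correlation_set",
        statistic=observed, p_value=(b_count + 1) / (B + 1),
        n_resamples=B, seed=seed)


# -- Jonckheere-Terpstra ------------------------------------------------------

def _jt_statistic(groups: list[np.ndarray]) -> float:
    """JT statistic: sum over ordered group pairs of Mann-Whitney counts,
    ties counted 1/2."""
    stat = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = groups[j][None, :] - groups[i][:, None]
            stat += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(stat)


def _jt_enumerate(pooled: np.ndarray, sizes: list[int],
                  observed: float) -> tuple[int, int]:
    """Exact tail count over all distinct assignments of the pooled
    values to ordered groups of the given sizes.

    Uses a precomputed pairwise comparison matrix C[p, q] =
    1*(v_p < v_q) + 0.5*(v_p == v_q); when group k is chosen from the
    remaining indices its JT contribution is the C-sum from the chosen
    indices to the rest, accumulated along the recursion.
    """
    n = len(pooled)
    C = ((pooled[:, None] < pooled[None, :]).astype(float)
         + 0.5 * (pooled[:, None] == pooled[None, :]))
    np.fill_diagonal(C, 0.0)
    count = [0]
    total = [0]
    tol = 1e-9

    def recurse(remaining: tuple, k: int, partial: float) -> None:
        if k == len(sizes) - 1:  # last group fully determined
            total[0] += 1
            if partial >= observed - tol:
                count[0] += 1
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            combo_set = set(combo)
            rest = tuple(i for i in remaining if i not in combo_set)
            contribution = C[np.ix_(combo, rest)].sum()
            recurse(rest, k + 1, partial + contribution)

    recurse(tuple(range(n)), 0, 0.0)
    # identical pooled values can make index-level assignments collide on
    # values; the tail proportion is unaffected, so report index counts
    return count[0], total[0]


def _jt_normal_p(groups: list[np.ndarray], observed: float) -> float:
    """Normal approximation with tie-corrected variance (one-sided,
    large-statistic tail)."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ns = np.array([len(g) for g in groups], dtype=float)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (N * N - np.sum(ns ** 2)) / 4.0
    term1 = (N * (N - 1) * (2 * N + 5)
             - np.sum(ns * (ns - 1) * (2 * ns + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(ns * (ns - 1) * (ns - 2)) * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * N * (N - 1) * (N - 2)))
    term3 = (np.sum(ns * (ns - 1)) * np.sum(t * (t - 1))
             / (8.0 * N * (N - 1)))
    var = term1 + term2 + term3
    if var <= 0:
        return 1.0
    z = (observed - mean) / math.sqrt(var)
    return float(stats.norm.sf(z))


def jonckheere_terpstra(groups, alternative: str = "increasing",
                        method: str = "auto", B: int = 10_000,
                        seed: int = 0) -> ResamplingTestResult:
    """One-sided Jonckheere-Terpstra trend test across ordered groups.

    ``alternative='increasing'`` tests for values rising along the group
    order, ``'decreasing'`` for falling.  ``method``: 'exact' (full
    enumeration, allowed up to 10^6 distinct assignments), 'permutation'
    (B shuffles, add-one p) or 'normal' (tie-corrected normal
    approximation).  'auto' picks exact below 5*10^4 assignments, else
    permutation.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise ValueError("need >=2 non-empty ordered groups")
    if alternative == "decreasing":
        gs = gs[::-1]
    elif alternative != "increasing":
        raise ValueError(f"unknown alternative {alternative!r}")
    sizes = [len(g) for g in gs]
    pooled = np.concatenate(gs)
    observed = _jt_statistic(gs)
    n_arrangements = math.factorial(len(pooled))
    for s in sizes:
        n_arrangements //= math.factorial(s)

    if method == "auto":
        method = ("exact" if n_arrangements <= AUTO_EXACT_LIMIT
                  else "permutation")
    logger.info("JT test: %s mode (%d arrangements)", method, n_arrangements)

    if method == "exact":
        if n_arrangements > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"{n_arrangements} arrangements exceed the exact limit")
        count, total = _jt_enumerate(pooled, sizes, observed)
        return ResamplingTestResult(
            method="jonckheere_terpstra_exact", statistic=observed,
            p_value=count / total, n_resamples=total, seed=None,
            extra={"alternative": alternative})
    if method == "permutation":
        rng = np.random.default_rng(seed)
        b_count = 0
        bounds = np.cumsum([0] + sizes)
        n = len(pooled)
        for start in range(0, B, 500):
            batch = min(500, B - start)
            perms = pooled[np.argsort(rng.random((batch, n)), axis=1)]
            stat = np.zeros(batch)
            for i in range(len(sizes)):
                gi = perms[:, bounds[i]:bounds[i + 1]]
                for j in range(i + 1, len(sizes)):
                    gj = perms[:, bounds[j]:bounds[j + 1]]
                    diff = gj[:, None, :] - gi[:, :, None]
                    stat += (diff > 0).sum(axis=(1, 2)) \
                        + 0.5 * (diff == 0).sum(axis=(1, 2))
            b_count += int(np.sum(stat >= observed - 1e-9))
        return ResamplingTestResult(
            method="jonckheere_terpstra_permutation", statistic=observed,
            p_value=(b_count + 1) / (B + 1), n_resamples=B, seed=seed,
            extra={"alternative": alternative})
    if method == "normal":
        return ResamplingTestResult(
            method="jonckheere_terpstra_normal", statistic=observed,
            p_value=max(min(_jt_normal_p(gs, observed), 1.0), 1e-300),
            extra={"alternative": alternative})
    raise ValueError(f"unknown method {method!r}")


# -- pre-registration null simulation -----------------------------------------

def null_simulation_study(n_patients: int = 20, n_drugs: int = 12,
                          genes_range: tuple = (5, 10), reps: int = 1000,
                          seed: int = 0,
                          cn_values=tuple(range(1, 7))) -> dict:
    """Simulate the multiple-testing landscape under the null.

    Each replicate draws an independent drug-response matrix (standard
    normal) and a copy-number matrix (uniform over ``cn_values``), with
    the gene count uniform over ``genes_range`` inclusive, and records
    the min / max / mean absolute Pearson correlation over all drug x
    gene pairs.  Returns per-replicate arrays plus their means — the
    expected span of spurious |r| at the study's size.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for stable summaries")
    if n_patients < 4:
        raise ValueError("n_patients < 4: correlations unstable")
    rng = np.random.default_rng(seed)
    lo, hi = genes_range
    maxs = np.empty(reps)
    mins = np.empty(reps)
    means = np.empty(reps)
    cn_values = np.asarray(cn_values, dtype=float)
    for r in range(reps):
        n_genes = int(rng.integers(lo, hi + 1))
        drugs = rng.standard_normal((n_patients, n_drugs))
        cn = rng.choice(cn_values, size=(n_patients, n_genes))
        d = drugs - drugs.mean(axis=0)
        c = cn - cn.mean(axis=0)
        denom = np.outer(np.linalg.norm(d, axis=0), np.linalg.norm(c, axis=0))
        with np.errstate(invalid="ignore"):
            corr = np.abs(d.T @ c) / denom
        corr = corr[np.isfinite(corr)]
        maxs[r], mins[r], means[r] = corr.max(), corr.min(), corr.mean()
    return {
        "per_replicate": {"max_abs_r": maxs, "min_abs_r": mins,
                          "mean_abs_r": means},
        "mean_max_abs_r": float(maxs.mean()),
        "mean_min_abs_r": float(mins.mean()),
        "mean_mean_abs_r": float(means.mean()),
        "n_patients": n_patients, "n_drugs": n_drugs,
        "genes_range": genes_range, "reps": reps, "seed": seed,
    }


# -- KS uniformity sensitivity ------------------------------------------------

def ks_uniformity_sensitivity(observed_pvalues, candidate_universe,
                              n_random_sets: int = 1000,
                              seed: int = 0) -> dict:
    """One-sample KS test of p-values against Uniform(0,1), with a
    sensitivity comparison against random same-size association sets.

    ``candidate_universe``: pool of p-values from all candidate gene-drug
    associations; ``n_random_sets`` same-size sets are drawn from it
    without replacement and their KS p-values form the reference
    distribution.  Returns observed KS statistic/p, the null KS p array,
    and the percentile of the observed p within it.
    """
    obs = np.asarray(observed_pvalues, dtype=float)
    if len(obs) < 3:
        raise ValueError("need >=3 observed p-values")
    if np.any((obs <= 0) | (obs > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    universe = np.asarray(candidate_universe, dtype=float)
    if len(universe) < len(obs):
        raise ValueError("candidate universe smaller than the observed set")
    ks_stat, ks_p = stats.kstest(obs, "uniform")
    rng = np.random.default_rng(seed)
    null_ps = np.empty(n_random_sets)
    for i in range(n_random_sets):
        draw = rng.choice(universe, size=len(obs), replace=False)
        null_ps[i] = stats.kstest(draw, "uniform").pvalue
    percentile = float(np.mean(null_ps <= ks_p))
    return {"ks_statistic": float(ks_stat), "ks_p": float(ks_p),
            "null_ks_p": null_ps, "percentile_in_null": percentile,
            "n_random_sets": n_random_sets, "seed": seed}


# -- GSEA ---------------------------------------------------------------------

def _running_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum-deviation enrichment score of a ranked list.

    ``in_set``: boolean membership along the ranking; ``weights``:
    |ranking statistic| per gene.  Hit steps are weighted, miss steps are
    uniform; ES is the running-sum excursion of largest magnitude.
    """
    n = len(in_set)
    n_hit = int(in_set.sum())
    hit_w = weights * in_set
    denom_hit = hit_w.sum()
    if denom_hit == 0:
        hit_step = in_set / max(n_hit, 1)
    else:
        hit_step = hit_w / denom_hit
    miss_step = (~in_set) / (n - n_hit)
    running = np.cumsum(hit_step - miss_step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_enrichment(ranked_genes, ranking_stats, gene_set: GeneSet,
                    n_perm: int = 1000, seed: int = 0) -> ResamplingTestResult:
    """Classic weighted running-sum gene-set enrichment (weight exponent 1).

    ``ranked_genes``: identifiers ordered by the ranking statistic
    (descending); ``ranking_stats``: the statistic per gene, same order.
    The null permutes gene labels (random same-size sets); NES = ES
    divided by the mean |permuted ES| of the same sign.  The p-value is
    the sign-conditional tail P(|ES_perm| >= |ES| | same sign) with the
    add-one rule — the standard two-sided GSEA convention (either
    direction of enrichment is detected; the tail is not doubled, which
    keeps the null rejection rate at its nominal level).
    """
    genes = list(ranked_genes)
    stats_arr = np.abs(np.asarray(ranking_stats, dtype=float))
    if not np.all(np.isfinite(stats_arr)):
        raise ValueError("ranking statistics must be finite")
    members = gene_set.members & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranked universe")
    if len(members) >= len(genes):
        raise ValueError("gene set covers the whole universe")
    in_set = np.array([g in members for g in genes])
    es = _running_es(in_set, stats_arr)
    rng = np.random.default_rng(seed)
    k = int(in_set.sum())
    n = len(genes)
    perm_es = np.empty(n_perm)
    idx = np.arange(n)
    for p in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(idx, size=k, replace=False)] = True
        perm_es[p] = _running_es(mask, stats_arr)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if len(same_sign):
        nes = es / np.mean(np.abs(same_sign))
        b = int(np.sum(np.abs(same_sign) >= abs(es) - 1e-12))
        p_val = (b + 1) / (len(same_sign) + 1)
    else:
        nes = float("nan")
        p_val = 1.0 / (n_perm + 1)
    return ResamplingTestResult(
        method="gsea", statistic=es, p_value=p_val,
        n_resamples=n_perm, seed=seed, sidedness="two-sided",
        extra={"nes": float(nes), "set_size": k, "universe_size": n})


# -- gene ranking for GSEA ----------------------------------------------------

def rank_genes_by_group_t(counts: pd.DataFrame, group_low, group_high,
                          cpm_threshold: float = 0.5,
                          max_low_fraction: float = 0.90,
                          log_counts: bool = False) -> pd.DataFrame:
    """Rank genes by the two-sample t-statistic between two sample groups.

    ``counts``: genes x samples expression counts (or, with
    ``log_counts=True``, already-log intensities that skip CPM filtering
    and log transform).  Genes with counts-per-million below
    ``cpm_threshold`` in more than ``max_low_fraction`` of the samples
    are discarded; remaining genes are ranked by the Welch t-statistic
    of high-vs-low group means on log2(CPM + 0.5), descending.
    Zero-variance-in-both-groups genes are dropped with a warning.
    """
    if len(group_low) < 2 or len(group_high) < 2:
        raise ValueError("both groups need >=2 samples")
    if log_counts:
        logm = counts
        kept = counts.index
    else:
        cpm = counts / counts.sum(axis=0) * 1e6
        low = (cpm < cpm_threshold).mean(axis=1)
        kept = counts.index[low <= max_low_fraction]
        n_drop = len(counts) - len(kept)
        if n_drop:
            logger.info("low-count filter removed %d/%d genes",
                        n_drop, len(counts))
        logm = np.log2(cpm.loc[kept] + 0.5)
    lo = logm[list(group_low)]
    hi = logm[list(group_high)]
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
    t = pd.Series(t, index=kept)
    bad = t.index[~np.isfinite(t)]
    if len(bad):
        logger.warning("dropping %d genes with undefined t-statistic",
                       len(bad))
        t = t.drop(index=bad)
    out = pd.DataFrame({"t": t}).sort_values("t", ascending=False)
    out.index.name = "gene"
    return out


# -- CN-expression correlation groups -----------------------------------------

def cn_expression_correlation_groups(
        expr: pd.DataFrame, cn: pd.DataFrame,
        is_cancer_gene: pd.Series,
        alteration_frequency: pd.Series,
        prevalence_threshold: float = 0.05) -> dict:
    """Per-gene Spearman correlation between expression and copy number,
    compared across driver/non-driver x prevalent/non-prevalent groups.

    Genes are 'prevalent' when their cohort SCNA frequency exceeds
    ``prevalence_threshold`` (sweepable); 'drivers' are cancer genes that
    are also prevalent.  Pairwise two-sided Mann-Whitney rank-sum tests
    compare the correlation distributions between all group pairs.
    Constant expression or CN leaves that gene's rho missing.
    """
    if not expr.index.equals(cn.index) or not expr.columns.equals(cn.columns):
        raise ValueError("expression and CN matrices must be aligned")
    rho = pd.Series(index=expr.index, dtype=float)
    for gene in expr.index:
        e = expr.loc[gene].values
        c = cn.loc[gene].values
        if np.std(e) == 0 or np.std(c) == 0:
            continue
        rho[gene] = stats.spearmanr(e, c).statistic
    cancer = is_cancer_gene.reindex(expr.index)
    cancer = cancer.where(cancer.notna(), False).astype(bool)
    prevalent = (alteration_frequency.reindex(expr.index).fillna(0.0)
                 > prevalence_threshold)
    group = pd.Series("noncancer_nonprevalent", index=expr.index, dtype=object)
    group[cancer & prevalent] = "driver"
    group[cancer & ~prevalent] = "cancer_nonprevalent"
    group[~cancer & prevalent] = "noncancer_prevalent"
    pairs = []
    names = ["driver", "cancer_nonprevalent", "noncancer_prevalent",
             "noncancer_nonprevalent"]
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            a = rho[(group == gi) & rho.notna()]
            b = rho[(group == gj) & rho.notna()]
            if len(a) == 0 or len(b) == 0:
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            pairs.append({"group_a": gi, "group_b": gj,
                          "u": float(res.statistic),
                          "p": float(res.pvalue),
                          "median_a": float(a.median()),
                          "median_b": float(b.median())})
    return {"rho": rho, "group": group,
            "pairwise": pd.DataFrame(pairs)}


# -- bivariate prediction ellipse ---------------------------------------------

@dataclass
class PredictionEllipse:
    center: np.ndarray
    axes: np.ndarray       # semi-axis lengths, descending
    rotation: float        # radians, principal axis vs x-axis
    level: float
    degenerate: bool = False


def normal_quantile_transform(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal quantiles of their probability
    points (rank-based normalization; mid-ranks for ties)."""
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (len(v) + 1))


def prediction_ellipse(x, y, level: float = 0.95) -> PredictionEllipse:
    """Bivariate-normal prediction ellipse at the given coverage level.

    The ellipse is {v : (v - mu)' Sigma^-1 (v - mu) <= q} with mu and
    Sigma the sample mean and covariance and q the ``level`` quantile of
    a chi-square with 2 degrees of freedom.  A singular covariance gives
    a degenerate (segment) result, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >=3 paired points")
    mu = np.array([x.mean(), y.mean()])
    cov = np.cov(x, y)
    q = stats.chi2.ppf(level, df=2)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = evals[-1] <= 1e-12 * max(evals[0], 1.0)
    axes = np.sqrt(np.clip(evals, 0, None) * q)
    rotation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    if degenerate:
        logger.warning("singular covariance: degenerate ellipse (segment)")
    return PredictionEllipse(center=mu, axes=axes, rotation=rotation,
                             level=level, degenerate=degenerate)


# -- ordered contingency association ------------------------------------------

def ordered_cn_association(table) -> dict:
    """Association between two ordered copy-number factors.

    ``table``: contingency counts (rows = gene ACN levels, columns =
    marker ACN levels).  Returns the Pearson chi-square p (levels as
    unordered factors) and the linear-by-linear ordered statistic
    M^2 = (N - 1) r^2 with equally spaced integer scores on both margins,
    referenced to chi-square with 1 df.  Zero-margin levels are dropped
    with a warning.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need a contingency table of at least 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must hold non-negative integer counts")
    row_keep = tab.sum(axis=1) > 0
    col_keep = tab.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.warning("dropping zero-margin levels: rows %s, cols %s",
                       np.nonzero(~row_keep)[0], np.nonzero(~col_keep)[0])
        tab = tab[row_keep][:, col_keep]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("fewer than 2 non-empty levels on a margin")
    chi2_res = stats.chi2_contingency(tab, correction=False)
    n = tab.sum()
    r_scores = np.arange(tab.shape[0], dtype=float)
    c_scores = np.arange(tab.shape[1], dtype=float)
    pr = tab.sum(axis=1) / n
    pc = tab.sum(axis=0) / n
    mr = np.sum(r_scores * pr)
    mc = np.sum(c_scores * pc)
    sr = math.sqrt(np.sum((r_scores - mr) ** 2 * pr))
    sc = math.sqrt(np.sum((c_scores - mc) ** 2 * pc))
    cov = np.sum(tab / n * np.outer(r_scores - mr, c_scores - mc))
    r = cov / (sr * sc) if sr > 0 and sc > 0 else 0.0
    m2 = (n - 1) * r * r
    return {"chi2_statistic": float(chi2_res.statistic),
            "chi2_p": float(chi2_res.pvalue),
            "ordered_statistic": float(m2),
            "ordered_p": float(stats.chi2.sf(m2, df=1)),
            "pearson_r": float(r), "n": int(n)}


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for exploratory sweeps.

    Off by default everywhere: the pre-specified association set is
    reported without multiplicity correction.
    """
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# -- pre-specified association testing ----------------------------------------

def linear_trend_test(x, y, direction: str) -> ResamplingTestResult:
    """One-sided Wald t-test of the slope of y on x.

    ``direction='sensitizing'`` expects a negative slope (higher copy
    number, lower AUC); ``'resistant'`` a positive one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need >=4 observations for the trend test")
    res = stats.linregress(x, y)
    want_negative = direction == "sensitizing"
    if (res.slope < 0) == want_negative:
        p = res.pvalue / 2
    else:
        p = 1 - res.pvalue / 2
    return ResamplingTestResult(
        method="linear_trend", statistic=float(res.slope),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        sidedness=f"one-sided ({direction})",
        extra={"r": float(res.rvalue), "stderr": float(res.stderr)})


def test_prespecified_associations(
        specs: list[AssociationSpec],
        rcn: pd.DataFrame, acn_levels: pd.DataFrame,
        auc_table: pd.DataFrame,
        exclude_samples=()) -> pd.DataFrame:
    """Test each pre-specified gene-drug association two ways.

    Per spec: (i) a one-sided linear trend test of AUC on log2 RCN and
    (ii) a one-sided Jonckheere-Terpstra test of AUC across the 3-level
    ACN ('2' < '3' < '4+'), both in the spec's direction ('sensitizing':
    response improves, i.e. AUC falls, with copy number).  ``rcn`` /
    ``acn_levels``: genes x samples; ``auc_table``: samples x drugs.
    ``exclude_samples`` removes configured non-independent or
    high-variability samples first.  Specs with <4 usable samples are
    reported untestable (NaN p-values).
    """
    rows = []
    for spec in specs:
        if spec.gene not in rcn.index or spec.drug not in auc_table.columns:
            raise ValueError(f"spec {spec.gene}/{spec.drug} not in data")
        samples = [s for s in auc_table.index
                   if s not in set(exclude_samples)]
        auc_vals = auc_table.loc[samples, spec.drug]
        gene_rcn = rcn.loc[spec.gene, samples]
        ok = auc_vals.notna() & gene_rcn.notna()
        row = {"gene": spec.gene, "drug": spec.drug,
               "direction": spec.direction, "n": int(ok.sum())}
        if ok.sum() < 4:
            row.update({"trend_slope": np.nan, "trend_p": np.nan,
                        "jt_statistic": np.nan, "jt_p": np.nan,
                        "untestable": True})
            rows.append(row)
            continue
        trend = linear_trend_test(gene_rcn[ok].values,
                                  auc_vals[ok].values, spec.direction)
        levels = acn_levels.loc[spec.gene, auc_vals[ok].index]
        groups = [auc_vals[ok][levels == lv].values
                  for lv in ("2", "3", "4+")]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 2:
            # sensitizing: AUC decreases across increasing ACN levels
            alt = ("decreasing" if spec.direction == "sensitizing"
                   else "increasing")
            jt = jonckheere_terpstra(groups, alternative=alt)
            jt_stat, jt_p = jt.statistic, jt.p_value
        else:
            jt_stat, jt_p = np.nan, np.nan
        row.update({"trend_slope": trend.statistic, "trend_p": trend.p_value,
                    "jt_statistic": jt_stat, "jt_p": jt_p,
                    "untestable": False})
        rows.append(row)
    return pd.DataFrame(rows)
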