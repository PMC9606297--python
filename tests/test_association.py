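"""Resampling tests, trend tests, enrichment scores and ellipse geometry."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scna import association, synthetic
from scna.association import (
    AssociationSpec, GeneSet, bootstrap_correlation_set_test,
    gsea_enrichment, jonckheere_terpstra, ks_uniformity_sensitivity,
    linear_trend_test, null_simulation_study, ordered_cn_association,
    permutation_cooccurrence_test, permutation_mean_difference_test,
    prediction_ellipse, rank_genes_by_group_t,
    cn_expression_correlation_groups,
)
# aliased so pytest does not collect the library function as a test
from scna.association import \
    test_prespecified_associations as prespecified_associations


def brute_force_permutation_p(a, b):
    """Exhaustive one-sided permutation p for mean(a) - mean(b)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = a.mean() - b.mean()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        stat = pooled[sel].mean() - pooled[~sel].mean()
        count += stat >= observed - 1e-12
        total += 1
    return count / total


class TestPermutationMeanDifference:
    def test_identical_groups_p_one(self):
        res = permutation_mean_difference_test(
            np.ones(5), np.ones(7), R=199, seed=0)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        # 3+3 instance: 20 label assignments
        a = rng.standard_normal(3)
        b = rng.standard_normal(3) + 1.0
        exact = brute_force_permutation_p(a, b)
        res = permutation_mean_difference_test(a, b, R=20_000, seed=1)
        # add-one Monte-Carlo estimate converges to the exact tail
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_add_one_floor(self):
        # complete separation: smallest attainable p is 1/(R+1)
        res = permutation_mean_difference_test(
            np.full(6, 10.0), np.zeros(6), R=199, seed=2)
        assert res.p_value >= 1 / 200
        assert res.p_value <= 4 / 200

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_mean_difference_test(np.array([]), np.ones(3))

    def test_seed_reproducibility(self):
        a, b = np.arange(5.0), np.arange(5.0) + 0.5
        r1 = permutation_mean_difference_test(a, b, R=500, seed=7)
        r2 = permutation_mean_difference_test(a, b, R=500, seed=7)
        assert r1.p_value == r2.p_value


class TestCooccurrencePermutation:
    def test_planted_effect_detected(self):
        m, truth = synthetic.simulate_cohort_genotypes(
            synthetic.GenotypeSimConfig(n_samples=300,
                                        co_occurrence_log_odds=2.0, seed=5))
        labels = {g: g in truth["pathway_genes"] for g in m.genes}
        res = permutation_cooccurrence_test(m, "MYC", labels, R=499, seed=6)
        assert res.p_value < 0.05

    def test_power_at_large_log_odds(self):
        rej = 0
        n = 50
        for seed in range(n):
            m, truth = synthetic.simulate_cohort_genotypes(
                synthetic.GenotypeSimConfig(
                    n_samples=300, co_occurrence_log_odds=2.0, seed=seed))
            labels = {g: g in truth["pathway_genes"] for g in m.genes}
            res = permutation_cooccurrence_test(m, "MYC", labels, R=199,
                                                seed=seed + 10_000)
            rej += res.p_value < 0.05
        assert rej / n >= 0.8

    def test_no_myc_amplification_refused(self):
        m, truth = synthetic.simulate_cohort_genotypes(
            synthetic.GenotypeSimConfig(n_samples=50, myc_amp_fraction=0.0,
                                        seed=1))
        labels = {g: g in truth["pathway_genes"] for g in m.genes}
        with pytest.raises(ValueError, match="empty group"):
            permutation_cooccurrence_test(m, "MYC", labels, R=99, seed=0)


class TestBootstrap:
    def test_same_values_p_near_half(self):
        vals = np.linspace(0, 1, 20)
        res = bootstrap_correlation_set_test(vals, vals.copy(), B=2000,
                                             seed=3)
        assert 0.4 < res.p_value < 0.6

    def test_complete_separation_floor(self):
        res = bootstrap_correlation_set_test(
            np.full(10, 0.9), np.full(10, 0.1), B=999, seed=4)
        assert res.p_value == 1 / 1000

    def test_consistency_with_larger_b(self, rng):
        w = rng.normal(0.4, 0.2, size=12)
        c = rng.normal(0.2, 0.2, size=25)
        p_small = bootstrap_correlation_set_test(w, c, B=2000, seed=5).p_value
        p_big = bootstrap_correlation_set_test(w, c, B=20_000, seed=6).p_value
        # binomial Monte-Carlo error of the smaller run
        se = math.sqrt(p_big * (1 - p_big) / 2000)
        assert abs(p_small - p_big) < 4 * se + 1e-3


class TestJonckheereTerpstra:
    def test_exact_ordered_example(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]],
                                  alternative="increasing")
        assert res.method == "jonckheere_terpstra_exact"
        assert res.statistic == 12.0
        assert res.p_value == pytest.approx(1 / 90)

    def test_all_identical_p_one(self):
        res = jonckheere_terpstra([[2, 2], [2, 2], [2, 2]])
        assert res.p_value == 1.0

    def test_reversed_alternative_large_tail(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]],
                                  alternative="decreasing")
        assert res.p_value >= 1 - 1 / 90

    def test_permutation_matches_exact(self, rng):
        groups = [rng.standard_normal(4), rng.standard_normal(4) + 0.5,
                  rng.standard_normal(4) + 1.0]
        exact = jonckheere_terpstra(groups, method="exact")
        perm = jonckheere_terpstra(groups, method="permutation", B=20_000,
                                   seed=9)
        assert perm.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2, 3]])

    def test_normal_approximation_reasonable(self, rng):
        groups = [rng.standard_normal(15), rng.standard_normal(15) + 0.8,
                  rng.standard_normal(15) + 1.6]
        perm = jonckheere_terpstra(groups, method="permutation", B=20_000,
                                   seed=11)
        norm = jonckheere_terpstra(groups, method="normal")
        assert norm.p_value == pytest.approx(perm.p_value, abs=0.02)


class TestNullSimulation:
    def test_study_scale_span(self):
        res = null_simulation_study(reps=400, seed=123)
        assert res["mean_max_abs_r"] == pytest.approx(0.6, abs=0.05)
        assert res["mean_min_abs_r"] == pytest.approx(0.0, abs=0.05)

    def test_large_n_shrinks_max(self):
        res = null_simulation_study(n_patients=2000, reps=100, seed=3)
        assert res["mean_max_abs_r"] < 0.1

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            null_simulation_study(n_patients=3)


class TestKSUniformity:
    def test_all_low_pvalues_reject(self, rng):
        universe = rng.uniform(size=300)
        res = ks_uniformity_sensitivity(np.full(14, 0.001), universe,
                                        n_random_sets=100, seed=0)
        assert res["ks_p"] < 1e-6

    def test_enriched_set_below_random_sets(self):
        hits = 0
        n_runs = 25
        for i in range(n_runs):
            rng = np.random.default_rng(400 + i)
            universe = rng.uniform(size=500)
            observed = rng.beta(0.3, 1.0, size=14)
            res = ks_uniformity_sensitivity(
                np.clip(observed, 1e-9, 1.0), universe,
                n_random_sets=200, seed=i)
            hits += res["percentile_in_null"] <= 0.05
        assert hits / n_runs >= 0.8

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            ks_uniformity_sensitivity([0.5, 0.0, 0.2], np.ones(10) * 0.5)


def brute_force_es(genes, stats_desc, members):
    """Direct running-sum recomputation of the weighted enrichment score."""
    weights = np.abs(np.asarray(stats_desc, dtype=float))
    hit = np.array([g in members for g in genes])
    nr = weights[hit].sum()
    n_miss = (~hit).sum()
    running = 0.0
    best = 0.0
    for i in range(len(genes)):
        if hit[i]:
            running += weights[i] / nr if nr > 0 else 1.0 / hit.sum()
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def _universe(self, rng, n=20):
        statv = np.sort(rng.standard_normal(n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        return genes, statv

    def test_top_k_set_positive_and_matches_bruteforce(self, rng):
        genes, statv = self._universe(rng)
        members = genes[:5]
        res = gsea_enrichment(genes, statv, GeneSet("top", members),
                              n_perm=99, seed=0)
        assert res.statistic > 0
        assert res.statistic == pytest.approx(
            brute_force_es(genes, statv, set(members)))

    def test_bottom_k_set_negative(self, rng):
        genes, statv = self._universe(rng)
        res = gsea_enrichment(genes, statv, GeneSet("bottom", genes[-5:]),
                              n_perm=99, seed=0)
        assert res.statistic < 0

    def test_random_universes_match_bruteforce(self):
        for i in range(50):
            rng = np.random.default_rng(900 + i)
            n = int(rng.integers(8, 21))
            genes, statv = self._universe(rng, n=n)
            k = int(rng.integers(2, n - 1))
            members = list(rng.choice(genes, size=k, replace=False))
            res = gsea_enrichment(genes, statv, GeneSet("s", members),
                                  n_perm=19, seed=i)
            assert res.statistic == pytest.approx(
                brute_force_es(genes, statv, set(members)), abs=1e-12)

    def test_full_universe_rejected(self, rng):
        genes, statv = self._universe(rng)
        with pytest.raises(ValueError):
            gsea_enrichment(genes, statv, GeneSet("all", genes))


class TestRankGenes:
    def _counts(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(20, 10)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(10)])
        return counts

    def test_gene_only_in_high_group_tops_ranking(self, rng):
        counts = self._counts(rng)
        low = [f"s{j}" for j in range(5)]
        high = [f"s{j}" for j in range(5, 10)]
        counts.loc["g0", low] = 0.0
        counts.loc["g0", high] = 500.0
        ranked = rank_genes_by_group_t(counts, low, high)
        assert ranked.index[0] == "g0"

    def test_low_count_filter(self, rng):
        # 20 samples, expressed in one: CPM < 0.5 in 95% of samples ->
        # removed (the filter drops genes low in more than 90%)
        counts = pd.DataFrame(
            rng.poisson(50, size=(20, 20)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(20)])
        counts.loc["g1"] = 0.0
        counts.loc["g1", "s0"] = 100.0
        ranked = rank_genes_by_group_t(
            counts, [f"s{j}" for j in range(10)],
            [f"s{j}" for j in range(10, 20)])
        assert "g1" not in ranked.index
        # a gene low in exactly 90% of samples stays
        counts.loc["g2"] = 0.0
        counts.loc["g2", [f"s{j}" for j in range(2)]] = 100.0
        ranked = rank_genes_by_group_t(
            counts, [f"s{j}" for j in range(10)],
            [f"s{j}" for j in range(10, 20)])
        assert "g2" in ranked.index

    def test_permuted_labels_symmetric_t(self, rng):
        counts = self._counts(rng)
        ranked = rank_genes_by_group_t(
            counts, [f"s{j}" for j in range(5)],
            [f"s{j}" for j in range(5, 10)])
        assert abs(ranked["t"].mean()) < 1.0


class TestCorrelationGroups:
    def test_exact_coupling_gives_rho_one(self):
        sim = synthetic.simulate_expression_cn(
            {"driver": 5, "other": 5}, {"driver": 1.0, "other": 1.0},
            n_samples=40, noise_sd=0.0, seed=0)
        out = cn_expression_correlation_groups(
            sim["expr"], sim["cn"],
            is_cancer_gene=pd.Series(True, index=sim["expr"].index),
            alteration_frequency=pd.Series(1.0, index=sim["expr"].index))
        assert np.allclose(out["rho"].dropna(), 1.0)

    def test_independent_matrices_rho_near_zero(self):
        sim = synthetic.simulate_expression_cn(
            {"other": 40}, {"other": 0.0}, n_samples=60, noise_sd=1.0,
            seed=1)
        out = cn_expression_correlation_groups(
            sim["expr"], sim["cn"],
            is_cancer_gene=pd.Series(False, index=sim["expr"].index),
            alteration_frequency=pd.Series(0.0, index=sim["expr"].index))
        assert abs(out["rho"].median()) < 0.15

    def test_driver_effect_detected_across_seeds(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            sim = synthetic.simulate_expression_cn(
                {"driver": 30, "other": 30},
                {"driver": 1.0, "other": 0.2},
                n_samples=50, noise_sd=1.0, seed=seed)
            cancer = sim["group"] == "driver"
            out = cn_expression_correlation_groups(
                sim["expr"], sim["cn"],
                is_cancer_gene=cancer,
                alteration_frequency=pd.Series(1.0,
                                               index=sim["expr"].index))
            pair = out["pairwise"]
            row = pair[(pair["group_a"] == "driver")
                       & (pair["group_b"] == "noncancer_prevalent")]
            hits += (row["p"].iloc[0] < 0.05
                     and row["median_a"].iloc[0] > row["median_b"].iloc[0])
        assert hits / n_runs >= 0.9


class TestPredictionEllipse:
    def test_identity_covariance_circle(self, rng):
        # large standard-normal sample: radius -> sqrt(chi2_{2,0.95})
        x = rng.standard_normal(200_000)
        y = rng.standard_normal(200_000)
        ell = prediction_ellipse(x, y)
        assert ell.axes[0] == pytest.approx(math.sqrt(5.9915), abs=0.02)
        assert ell.axes[1] == pytest.approx(math.sqrt(5.9915), abs=0.02)

    def test_high_correlation_axis_ratio(self):
        # exact rho = 0.99 correlation matrix: ratio sqrt(1.99/0.01)
        cov = np.array([[1.0, 0.99], [0.99, 1.0]])
        pts = np.linalg.cholesky(cov) @ np.random.default_rng(0)\
            .standard_normal((2, 500_000))
        ell = prediction_ellipse(pts[0], pts[1])
        assert ell.axes[0] / ell.axes[1] == pytest.approx(
            math.sqrt(1.99 / 0.01), rel=0.05)

    def test_rotation_equivariance(self, rng):
        x = rng.standard_normal(500)
        y = 0.5 * x + 0.3 * rng.standard_normal(500)
        base = prediction_ellipse(x, y)
        theta = 0.7
        xr = math.cos(theta) * x - math.sin(theta) * y
        yr = math.sin(theta) * x + math.cos(theta) * y
        rot = prediction_ellipse(xr, yr)
        assert np.allclose(sorted(rot.axes), sorted(base.axes), rtol=1e-9)
        diff = (rot.rotation - base.rotation - theta) % math.pi
        assert min(diff, math.pi - diff) == pytest.approx(0.0, abs=1e-6)

    def test_singular_covariance_flagged(self):
        x = np.arange(10.0)
        ell = prediction_ellipse(x, 2 * x)
        assert ell.degenerate


class TestOrderedAssociation:
    def test_perfect_diagonal_2x2(self):
        res = ordered_cn_association([[10, 0], [0, 10]])
        assert res["ordered_statistic"] == pytest.approx(19.0)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_zero_margin_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            res = ordered_cn_association([[5, 0, 5], [5, 0, 5]])
        assert res["n"] == 20

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            ordered_cn_association([[1.5, 2], [3, 4]])


class TestPrespecified:
    def _cohort(self, rng, slope=0.0, n=18):
        samples = [f"s{i}" for i in range(n)]
        acn_int = rng.integers(1, 7, size=n).astype(float)
        rcn = pd.DataFrame([np.log2(acn_int / 2.0)], index=["MYC"],
                           columns=samples)
        levels = pd.DataFrame(
            [[("2" if v <= 2 else "3" if v == 3 else "4+")
              for v in acn_int]], index=["MYC"], columns=samples)
        auc = pd.DataFrame(
            {"paclitaxel": slope * rcn.loc["MYC"].values
             + 0.1 * rng.standard_normal(n) + 0.6}, index=samples)
        return rcn, levels, auc

    def test_strictly_decreasing_minimal_p(self):
        n = 12
        samples = [f"s{i}" for i in range(n)]
        acn_int = np.repeat([2.0, 3.0, 4.0], 4)
        rcn = pd.DataFrame([np.log2(acn_int / 2.0)], index=["MYC"],
                           columns=samples)
        levels = pd.DataFrame([["2"] * 4 + ["3"] * 4 + ["4+"] * 4],
                              index=["MYC"], columns=samples)
        auc = pd.DataFrame({"pac": -np.arange(n, dtype=float)},
                           index=samples)
        res = prespecified_associations(
            [AssociationSpec("MYC", "pac", "sensitizing")],
            rcn, levels, auc)
        assert res.loc[0, "trend_p"] < 0.001
        # fully ordered arrangement: minimal attainable exact JT p
        assert res.loc[0, "jt_p"] == pytest.approx(
            1 / (math.factorial(12) // math.factorial(4) ** 3), rel=1e-9)

    def test_planted_negative_slope_detected(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(700 + seed)
            rcn, levels, auc = self._cohort(rng, slope=-0.15)
            res = prespecified_associations(
                [AssociationSpec("MYC", "paclitaxel", "sensitizing")],
                rcn, levels, auc)
            hits += res.loc[0, "trend_p"] < 0.05
        assert hits / n_runs > 0.5

    def test_untestable_with_few_samples(self, rng):
        rcn, levels, auc = self._cohort(rng)
        res = prespecified_associations(
            [AssociationSpec("MYC", "paclitaxel", "sensitizing")],
            rcn, levels, auc, exclude_samples=auc.index[3:])
        assert bool(res.loc[0, "untestable"])

    def test_shuffled_cn_null_calibrated(self):
        rej = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(5000 + seed)
            rcn, levels, auc = self._cohort(rng, slope=0.0)
            res = prespecified_associations(
                [AssociationSpec("MYC", "paclitaxel", "sensitizing")],
                rcn, levels, auc)
            rej += res.loc[0, "trend_p"] <= 0.05
        lo, hi = stats.binom.interval(0.999, n_runs, 0.05)
        assert lo <= rej <= hi


class TestLinearTrend:
    def test_direction_flip(self, rng):
        x = np.arange(10.0)
        y = -0.5 * x + 0.1 * rng.standard_normal(10)
        p_sens = linear_trend_test(x, y, "sensitizing").p_value
        p_res = linear_trend_test(x, y, "resistant").p_value
        assert p_sens < 0.01 < p_res
        assert p_sens + p_res == pytest.approx(1.0)


class TestBenjaminiHochberg:
    def test_known_adjustment(self):
        from scna.association import benjamini_hochberg
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        # BH: p_(i) * m / i, monotonised from the largest rank down
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        q2 = benjamini_hochberg([0.001, 0.5])
        assert q2 == pytest.approx([0.002, 0.5])
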