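"""Methylation-similarity scoring, the empirical null and the tree views."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from methclonal.clonality import (
    classify_pairs,
    concordance,
    count_adjacent_pairs,
    distance_group_stats,
    empirical_quantile_threshold,
    hierarchical_cluster,
    manhattan_distance,
    ms_score,
    null_distribution,
    score_correlation,
    threshold_consistency,
)
from methclonal.io import filter_complete_probes

from conftest import duo_annotation, tiny_beta


class TestDistanceAndScore:
    def test_unit_square_corners(self):
        assert manhattan_distance([0, 0], [1, 1]) == 2.0

    def test_symmetry_and_brute_force_oracle(self, rng):
        for _ in range(20):
            x, y = rng.random(10), rng.random(10)
            d = manhattan_distance(x, y)
            assert d == manhattan_distance(y, x)
            assert d == pytest.approx(sum(abs(a - b) for a, b in zip(x, y)))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            manhattan_distance([0.1], [0.1, 0.2])

    def test_inverse_distance_closed_form(self):
        assert ms_score([0, 0], [1, 1]) == 0.5

    def test_array_scale_magnitude(self):
        """0.05 everywhere over 27,573 probes gives MS in the 10^-4 range."""
        x = np.zeros(27_573)
        y = np.full(27_573, 0.05)
        assert ms_score(x, y) == pytest.approx(1 / 1378.65, rel=1e-12)
        assert 7.2e-4 < ms_score(x, y) < 7.3e-4

    def test_identical_profiles_are_infinitely_similar(self):
        x = np.full(5, 0.3)
        assert math.isinf(ms_score(x, x))
        assert classify_pairs([ms_score(x, x)], tau=1.0) == ["TR"]

    def test_probe_permutation_invariance(self, rng):
        x, y = rng.random(50), rng.random(50)
        perm = rng.permutation(50)
        assert ms_score(x, y) == pytest.approx(ms_score(x[perm], y[perm]))


class TestEmpiricalNull:
    def test_quantile_is_order_statistic_at_ceiling_rank(self):
        assert empirical_quantile_threshold(np.arange(1, 21)) == 19.0

    def test_constant_null_returns_the_constant(self):
        assert empirical_quantile_threshold(np.full(7, 3.3)) == 3.3

    def test_unrelated_combinatorics_m_times_m_minus_1(self, ptlr_cohort):
        _, data = ptlr_cohort
        beta = filter_complete_probes(data.beta)
        null = null_distribution(beta, data.annotation, "PT/LR")
        assert null.n_unrelated == 17 * 16
        assert null.scores.min() <= null.tau <= null.scores.max()

    def test_pair_relabeling_leaves_classification_invariant(self, ptlr_cohort):
        _, data = ptlr_cohort
        beta = filter_complete_probes(data.beta)
        null = null_distribution(beta, data.annotation, "PT/LR")
        shuffled = data.annotation.table.sample(frac=1, random_state=0)
        from methclonal.io import SampleAnnotation

        null2 = null_distribution(beta, SampleAnnotation(shuffled), "PT/LR")
        assert null2.tau == pytest.approx(null.tau)
        assert np.allclose(np.sort(null2.scores), np.sort(null.scores))


class TestClassification:
    def test_boundary_score_is_new_primary(self):
        assert classify_pairs([1.0, 1.0001], tau=1.0) == ["NP", "TR"]

    def test_all_below_threshold_all_np(self):
        assert classify_pairs([0.1, 0.2], tau=0.5) == ["NP", "NP"]

    def test_printed_scores_reproduce_printed_labels(self, fixtures):
        scores = np.array([p.ms_score for p in fixtures.pairs])
        for tau in (6.2e-4, 6.5e-4):
            assert classify_pairs(scores, tau) == [p.label_ms for p in fixtures.pairs]


class TestThresholdConsistency:
    def test_feasible_interval_of_the_printed_column(self, fixtures):
        scores = np.array([p.ms_score for p in fixtures.pairs])
        iv = threshold_consistency(scores, [p.label_ms for p in fixtures.pairs])
        assert iv.feasible
        assert iv.lower == pytest.approx(6.11e-4)
        assert iv.upper == pytest.approx(6.64e-4)

    def test_inconsistent_labels_flagged_infeasible(self):
        iv = threshold_consistency([1.0, 2.0], ["TR", "NP"])
        assert not iv.feasible

    def test_single_pair_yields_half_line(self):
        iv = threshold_consistency([5.0], ["TR"])
        assert iv.lower == -math.inf and iv.upper == 5.0


def brute_force_complete_linkage(x: np.ndarray):
    """Naive agglomeration: repeatedly merge the closest clusters by max-link."""
    clusters = [{i} for i in range(x.shape[0])]
    dist = lambda a, b: max(
        np.abs(x[i] - x[j]).sum() for i in a for j in b
    )
    heights = []
    while len(clusters) > 1:
        best = min(
            ((i, j) for i in range(len(clusters)) for j in range(i + 1, len(clusters))),
            key=lambda ij: dist(clusters[ij[0]], clusters[ij[1]]),
        )
        i, j = best
        heights.append(dist(clusters[i], clusters[j]))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] | clusters[j]]
        )
    return np.array(heights)


class TestHierarchicalClustering:
    def test_two_tight_duos_merge_first(self):
        m = tiny_beta(
            np.array([[0.1, 0.11, 0.9, 0.91], [0.2, 0.21, 0.8, 0.81]]),
            sample_ids=["a1", "a2", "b1", "b2"],
        )
        d = hierarchical_cluster(m)
        ann = duo_annotation([("a1", "a2"), ("b1", "b2")])
        assert count_adjacent_pairs(d, ann, "PT/LR") == 2

    def test_merge_heights_match_brute_force(self, rng):
        x = rng.random((6, 15))
        m = tiny_beta(x.T)
        d = hierarchical_cluster(m)
        assert np.allclose(np.sort(d.merges[:, 2]), np.sort(brute_force_complete_linkage(x)))

    def test_ultrametric_heights_nondecreasing(self, rng):
        x = rng.random((9, 12))
        d = hierarchical_cluster(tiny_beta(x.T))
        heights = d.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_newick_round_trips_leaf_names(self, rng):
        d = hierarchical_cluster(tiny_beta(rng.random((10, 5))))
        nwk = d.to_newick()
        assert nwk.endswith(";")
        for leaf in d.leaf_ids:
            assert leaf in nwk


def brute_force_adjacent(dendro, pairs):
    """A pair is adjacent iff its members are mutual direct merge partners."""
    n = len(dendro.leaf_ids)
    partner = {}
    for a, b, _, _ in dendro.merges:
        a, b = int(a), int(b)
        if a < n and b < n:
            partner[dendro.leaf_ids[a]] = dendro.leaf_ids[b]
            partner[dendro.leaf_ids[b]] = dendro.leaf_ids[a]
    return sum(partner.get(pt) == rec for pt, rec in pairs)


class TestPairAdjacency:
    def test_matches_mutual_partner_oracle_on_random_trees(self, rng):
        for _ in range(10):
            x = rng.random((8, 10))
            ids = [f"s{i}" for i in range(8)]
            m = tiny_beta(x.T, sample_ids=ids)
            d = hierarchical_cluster(m)
            pairs = [(ids[0], ids[1]), (ids[2], ids[3]), (ids[4], ids[5]), (ids[6], ids[7])]
            ann = duo_annotation(pairs)
            assert count_adjacent_pairs(d, ann, "PT/LR") == brute_force_adjacent(d, pairs)

    def test_independent_cohort_has_no_adjacent_pairs(self):
        from methclonal.simulate import CohortConfig, generate_cohort

        cfg = CohortConfig(
            n_probes=2_000, n_pairs=11, cohort="PT/CL", clonal_fraction=0.0,
            n_missing_probes=0, seed=41,
        )
        data = generate_cohort(cfg)
        d = hierarchical_cluster(data.beta)
        assert count_adjacent_pairs(d, data.annotation, "PT/CL") <= 1


class TestDistanceGroups:
    def test_group_sizes_combinatorics(self, ptlr_cohort):
        _, data = ptlr_cohort
        beta = filter_complete_probes(data.beta)
        groups, tests = distance_group_stats(beta, data.annotation, "PT/LR")
        m = 17
        assert groups["real"].size == m
        assert groups["artificial"].size == m * (m - 1)
        assert groups["primary"].size == m * (m - 1) // 2
        assert groups["recurrence"].size == m * (m - 1) // 2
        assert groups["normal"].size == 6 * 5 // 2
        assert {"real", "artificial"} <= set(tests["group_a"]) | set(tests["group_b"])

    def test_all_clonal_cohort_real_below_artificial(self):
        from methclonal.simulate import CohortConfig, generate_cohort

        cfg = CohortConfig(n_probes=1_500, n_pairs=10, cohort="PT/AM",
                           clonal_fraction=1.0, n_missing_probes=0, seed=42)
        data = generate_cohort(cfg)
        groups, tests = distance_group_stats(data.beta, data.annotation, "PT/AM")
        assert groups["real"].mean() < groups["artificial"].mean()
        row = tests[(tests["group_a"] == "real") & (tests["group_b"] == "artificial")]
        assert float(row["p_value"].iloc[0]) < 0.05

    def test_all_independent_cohort_real_vs_artificial_not_significant(self):
        """Contralateral-like cohorts: matched pairs look unrelated."""
        from methclonal.simulate import CohortConfig, generate_cohort

        pvals = []
        for seed in range(20):
            cfg = CohortConfig(n_probes=400, n_pairs=11, cohort="PT/CL",
                               clonal_fraction=0.0, n_missing_probes=0, seed=300 + seed)
            data = generate_cohort(cfg)
            _, tests = distance_group_stats(data.beta, data.annotation, "PT/CL")
            row = tests[(tests["group_a"] == "real") & (tests["group_b"] == "artificial")]
            pvals.append(float(row["p_value"].iloc[0]))
        assert np.median(pvals) > 0.05


class TestDivergenceDegradation:
    def test_tr_recovery_degrades_monotonically_in_divergence(self):
        """Growing clonal drift erodes sensitivity toward zero."""
        from methclonal.simulate import CohortConfig, generate_cohort

        mean_sens = []
        for d in (0.005, 0.08, 0.2):
            sens = []
            for seed in range(5):
                cfg = CohortConfig(
                    n_probes=1_500, n_pairs=12, clonal_fraction=0.5, divergence=d,
                    tumor_alteration_rate=0.2, n_missing_probes=0, seed=1_100 + seed,
                )
                data = generate_cohort(cfg)
                b = data.beta
                null = null_distribution(b, data.annotation, "PT/LR")
                pairs = data.annotation.complete_pairs("PT/LR")
                scores = np.array(
                    [ms_score(b.values[p].to_numpy(), b.values[r].to_numpy())
                     for _, p, r in pairs]
                )
                labels = classify_pairs(scores, null.tau)
                truth = list(data.truth["label"])
                sens.append(
                    sum(l == t == "TR" for l, t in zip(labels, truth))
                    / truth.count("TR")
                )
            mean_sens.append(np.mean(sens))
        assert mean_sens[0] >= mean_sens[1] >= mean_sens[2]
        assert mean_sens[0] > mean_sens[2]


class TestConcordance:
    def test_printed_ms_vs_pis_agreement(self, fixtures):
        ids = [p.pair_id for p in fixtures.pairs]
        c = concordance(
            [p.label_ms for p in fixtures.pairs],
            [p.label_pis for p in fixtures.pairs],
            ids,
        )
        assert (c.n_agree, c.n_total) == (14, 17)
        assert c.disagreements == ["4", "8", "14"]

    def test_printed_ms_vs_clinical_agreement(self, fixtures):
        ids = [p.pair_id for p in fixtures.pairs]
        c = concordance(
            [p.label_ms for p in fixtures.pairs],
            [p.label_clinical for p in fixtures.pairs],
            ids,
        )
        assert (c.n_agree, c.fraction) == (14, pytest.approx(14 / 17))
        assert c.disagreements == ["7", "8", "14"]

    def test_identical_columns_fully_agree(self):
        c = concordance(["TR"] * 9 + ["NP"] * 8, ["TR"] * 9 + ["NP"] * 8)
        assert (c.n_agree, c.fraction) == (17, 1.0)


class TestScoreCorrelation:
    def test_perfect_linear_relation(self):
        out = score_correlation([2, 4, 6, 8], [1, 2, 3, 4])
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            score_correlation([1, 1, 1], [1, 2, 3])

    def test_r_on_printed_scores_matches_covariance_oracle(self, fixtures):
        ms = np.array([p.ms_score for p in fixtures.pairs])
        pis = np.array([p.pis_score for p in fixtures.pairs])
        out = score_correlation(ms, pis)
        cov = ((ms - ms.mean()) * (pis - pis.mean())).mean()
        r_oracle = cov / (ms.std() * pis.std())
        assert out["r"] == pytest.approx(r_oracle, rel=1e-12)
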