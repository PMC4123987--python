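"""Exact and approximate rank tests, BH correction and probe ranking."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methclonal.dmp import (
    bh_adjust,
    count_significant,
    differential_methylation,
    paired_wilcoxon,
    rank_dmps,
    unpaired_wilcoxon,
)
from methclonal.io import filter_complete_probes


def brute_force_signed_rank_p(diff: np.ndarray) -> float:
    """Enumerate all 2^n sign assignments of the |difference| midranks."""
    d = diff[diff != 0.0]
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    sums = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=d.size)]
    )
    cdf = (sums <= w + 1e-9).mean()
    sf = (sums >= w - 1e-9).mean()
    return min(1.0, 2.0 * min(cdf, sf))


def brute_force_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Enumerate all C(n, n_a) group labelings of the pooled sample."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = ranks[: a.size].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(pooled.size), a.size)]
    )
    cdf = (sums <= obs + 1e-9).mean()
    sf = (sums >= obs - 1e-9).mean()
    return min(1.0, 2.0 * min(cdf, sf))


class TestPairedWilcoxon:
    def test_all_zero_differences_give_p_one(self):
        assert paired_wilcoxon(np.zeros(10)) == 1.0

    def test_twenty_consistent_signs_hit_exact_tail(self):
        p = paired_wilcoxon(np.linspace(0.1, 1.0, 20))
        assert p == pytest.approx(2.0 * 2.0**-20, rel=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        # integer-valued differences exercise ties and zeros
        diff = rng.integers(-4, 5, size=n).astype(float)
        if (diff == 0).all():
            diff[0] = 1.0
        assert paired_wilcoxon(diff) == pytest.approx(
            brute_force_signed_rank_p(diff), abs=1e-12
        )

    def test_matrix_path_agrees_with_scalar_path(self, rng):
        diff = rng.normal(size=(40, 12))
        diff[3, 0] = 0.0  # force one row through the zero-handling path
        diff[5, 1] = diff[5, 2]  # and one through the tie path
        rowwise = paired_wilcoxon(diff)
        scalar = np.array([paired_wilcoxon(diff[i]) for i in range(40)])
        assert np.allclose(rowwise, scalar, atol=1e-12)

    def test_large_n_approximation_tracks_scipy(self, rng):
        diff = rng.normal(0.2, 1.0, size=40)
        ours = paired_wilcoxon(diff)
        ref = stats.wilcoxon(diff, correction=True, method="approx").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestUnpairedWilcoxon:
    def test_identical_multisets_give_p_one(self):
        assert unpaired_wilcoxon([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_separated_triples_exact(self):
        assert unpaired_wilcoxon([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_label_permutation_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 11 - n_a))
        # tie-free continuous draws
        a = rng.normal(size=n_a)
        b = rng.normal(0.5, 1.0, size=n_b)
        assert unpaired_wilcoxon(a, b) == pytest.approx(
            brute_force_rank_sum_p(a, b), abs=1e-12
        )


class TestBhAdjust:
    def test_direct_min_formula_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_dominates_raw_p_and_permutation_equivariance(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_direct_step_up_oracle(self, rng):
        p = rng.random(30)
        order = np.argsort(p)
        m = p.size
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), oracle)


class TestBhProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_adjusted_values_dominate_and_preserve_order(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1.0 + 1e-12)).all()
        # q is nondecreasing along the sorted-p order
        assert (np.diff(q[np.argsort(p, kind="stable")]) >= -1e-12).all()


class TestRankingAndCounting:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "gene", "p_raw", "q", "delta_beta"])

    def test_equal_q_ranks_by_absolute_delta_beta(self):
        t = self._table(
            [("cgB", None, 0.01, 0.05, 0.1), ("cgA", None, 0.01, 0.05, -0.2)]
        )
        ranked = rank_dmps(t)
        assert list(ranked["probe_id"]) == ["cgA", "cgB"]

    def test_full_tie_breaks_lexicographically(self):
        t = self._table(
            [("cgC", None, 0.2, 0.4, 0.1), ("cgA", None, 0.2, 0.4, 0.1), ("cgB", None, 0.2, 0.4, 0.1)]
        )
        assert list(rank_dmps(t)["probe_id"]) == ["cgA", "cgB", "cgC"]

    def test_top_n_beyond_table_size_returns_all(self):
        t = self._table([("cgA", None, 0.2, 0.4, 0.1)])
        assert len(rank_dmps(t, top_n=50)) == 1

    def test_fdr_boundary_is_strict(self):
        t = self._table(
            [("cgA", None, 0.01, 0.05, 0.1), ("cgB", None, 0.01, 0.0499, 0.1), ("cgC", None, 1.0, 1.0, 0.0)]
        )
        assert count_significant(t, 0.05) == 1


class TestCohortLevelRecovery:
    def test_spiked_cohort_recovers_progression_probes(self, ptam_cohort):
        """Probes carrying the progression signature dominate the ranking."""
        cfg, data = ptam_cohort
        beta = filter_complete_probes(data.beta)
        res = differential_methylation(beta, data.annotation, "PT/AM")
        top = rank_dmps(res, cfg.progression_probes)
        spiked = {f"cg{i:08d}" for i in range(cfg.progression_probes)}
        assert len(spiked & set(top["probe_id"])) >= 0.9 * cfg.progression_probes
        assert count_significant(res) >= 0.8 * cfg.progression_probes

    def test_delta_beta_sign_matches_injected_signature(self, ptam_cohort):
        cfg, data = ptam_cohort
        from methclonal.simulate import _progression_signature

        beta = filter_complete_probes(data.beta)
        res = differential_methylation(beta, data.annotation, "PT/AM").set_index("probe_id")
        sig = _progression_signature(cfg)
        for i in range(0, cfg.progression_probes, 7):
            assert np.sign(res.loc[f"cg{i:08d}", "delta_beta"]) == np.sign(sig[i])
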