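"""Nonparametric statistics against independent brute-force oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from fbos.stats import (kruskal_wallis, paired_and_unpaired_rank_tests,
                        posthoc_rank, rank_correlation,
                        reproduce_paper_statistics)
from fbos.synthetic import CohortConfig, generate_cohort

# ---------------------------------------------------------------------------
# brute-force oracles (explicit rank arithmetic, exhaustive enumeration)
# ---------------------------------------------------------------------------


def _avg_ranks(values):
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sv = np.asarray(values)[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_kruskal(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _avg_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else np.nan


def brute_kendall_tau_b(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


def brute_spearman(x, y):
    rx, ry = _avg_ranks(x), _avg_ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def brute_ranksum_pvalue(a, b):
    """Exact two-sided rank-sum p by full enumeration (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = _avg_ranks(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    stats = [sum(c) for c in itertools.combinations(ranks, na)]
    stats = np.asarray(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
    return p


def brute_signrank_pvalue(a, b):
    """Exact two-sided signed-rank p by sign-flip enumeration (no ties)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = _avg_ranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(np.sum(ranks[np.array(signs, bool)]))
    ws = np.asarray(ws)
    mean = n * (n + 1) / 4
    p = np.mean(np.abs(ws - mean) >= abs(w_obs - mean) - 1e-12)
    return p


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestKruskalWallis:
    @pytest.mark.parametrize("groups", [
        ([1, 2, 3], [4, 5, 6], [7, 8, 9]),
        ([1.2, 3.4, 2.2, 5.0], [0.1, 0.2], [9.9, 1.1, 2.2]),
        ([1, 1, 2, 2], [2, 3, 3], [1, 4, 4, 4]),     # heavy ties
    ])
    def test_matches_hand_rank_formula(self, groups):
        groups = [np.asarray(g, float) for g in groups]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(brute_kruskal(groups), abs=1e-12)

    def test_separated_group_significant(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        c = rng.normal(loc=10.0, size=30)
        _, p = kruskal_wallis([a, b, c])
        assert p < 1e-3

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            x = rng.normal(size=60)
            ps.append(kruskal_wallis([x[:20], x[20:40], x[40:]])[1])
        ps = np.asarray(ps)
        # coarse uniformity: quartile occupancy within binomial bounds
        assert 0.10 < np.mean(ps < 0.25) < 0.45
        assert 0.10 < np.mean(ps > 0.75) < 0.45

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestPosthoc:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.normal(size=40)
        p = posthoc_rank([x, x.copy(), x.copy()], ["a", "b", "c"])
        assert all(v > 0.99 for v in p.values())

    def test_only_old_contrasts_significant(self, rng):
        young = rng.normal(0.22, 0.02, 38)
        middle = rng.normal(0.22, 0.02, 14)
        old = rng.normal(0.13, 0.02, 34)
        p = posthoc_rank([young, middle, old], ["young", "middle", "old"])
        assert p[("young", "old")] < 0.01
        assert p[("middle", "old")] < 0.01
        assert p[("young", "middle")] > 0.05

    def test_symmetry_in_pair_order(self, rng):
        gs = [rng.normal(size=10), rng.normal(size=12), rng.normal(size=8)]
        p = posthoc_rank(gs, ["a", "b", "c"])
        assert p[("a", "b")] == p[("b", "a")]

    def test_dunn_bonferroni_variant_runs(self, rng):
        gs = [rng.normal(size=10), rng.normal(1.5, 1, 12)]
        p = posthoc_rank(gs, ["a", "b"], method="dunn_bonferroni")
        assert 0 <= p[("a", "b")] <= 1


class TestRankCorrelation:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        for method in ("spearman", "kendall"):
            r, p, n = rank_correlation(x, x ** 3, method=method)
            assert r == pytest.approx(1.0)
            r, _, _ = rank_correlation(x, -x, method=method)
            assert r == pytest.approx(-1.0)

    def test_kendall_matches_pair_enumeration(self, rng):
        x = rng.integers(0, 5, size=12).astype(float)
        y = rng.integers(0, 4, size=12).astype(float)
        r, _, _ = rank_correlation(x, y, method="kendall")
        assert r == pytest.approx(brute_kendall_tau_b(x, y), abs=1e-12)

    def test_spearman_matches_rank_pearson(self, rng):
        x = rng.normal(size=11)
        y = rng.normal(size=11) + 0.5 * x
        r, _, _ = rank_correlation(x, y, method="spearman")
        assert r == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_missing_pairs_dropped_and_counted(self):
        x = np.array([1, 2, 3, 4, 5, np.nan])
        y = np.array([2, 1, 4, 3, np.nan, 6.0])
        _, _, n = rank_correlation(x, y)
        assert n == 4

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            rank_correlation([1, 2, 3], [3, 2, 1])


class TestRankTests:
    def test_identical_paired_samples(self):
        a = np.array([1.0, 2, 3, 4])
        assert paired_and_unpaired_rank_tests(a, a.copy(), paired=True) == 1.0

    def test_ranksum_matches_exact_enumeration(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([101.0, 102, 103, 104, 105])
        p = paired_and_unpaired_rank_tests(a, b, paired=False)
        assert p == pytest.approx(brute_ranksum_pvalue(a, b), abs=1e-12)
        # the minimal attainable two-sided p for n = 5, 5
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_ranksum_matches_enumeration_random(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(0.8, 1.0, size=5)
        p = paired_and_unpaired_rank_tests(a, b, paired=False)
        assert p == pytest.approx(brute_ranksum_pvalue(a, b), abs=1e-12)

    def test_signrank_matches_enumeration(self, rng):
        a = rng.normal(size=9)
        b = a + rng.normal(0.4, 1.0, size=9)
        p = paired_and_unpaired_rank_tests(a, b, paired=True)
        assert p == pytest.approx(brute_signrank_pvalue(a, b), abs=1e-12)

    def test_signrank_symmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert paired_and_unpaired_rank_tests(a, b, paired=True) == \
            pytest.approx(paired_and_unpaired_rank_tests(b, a, paired=True))

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_and_unpaired_rank_tests([1, 2], [1, 2, 3], paired=True)


class TestReport:
    def test_deterministic(self, default_cohort):
        _, table, _ = default_cohort
        r1 = reproduce_paper_statistics(table)
        r2 = reproduce_paper_statistics(table)
        assert r1.correlations == r2.correlations
        assert r1.group_summary.equals(r2.group_summary)

    def test_reported_n_excludes_missing(self, default_cohort):
        cfg, table, _ = default_cohort
        n_old = cfg.n_per_group["old"]
        rep = reproduce_paper_statistics(table)
        assert rep.correlations["spearman_length_walking_p"][2] == \
            n_old - cfg.n_walking_missing
        assert rep.correlations["kendall_area_sppb"][2] == n_old

    def test_missing_column_skipped_and_listed(self, default_cohort):
        _, table, _ = default_cohort
        rep = reproduce_paper_statistics(table.drop(columns=["sppb"]))
        assert "kendall_area_sppb" not in rep.correlations
        assert any("sppb" in s for s in rep.skipped)

    def test_null_cohort_age_correlation_small(self):
        # no group differences, no couplings: |rho| < 0.3 on >= 95% of seeds
        flat = {m: {g: d["young"] for g in ("young", "middle", "old")}
                for m, d in CohortConfig().metric_distributions.items()}
        hits = 0
        n_seeds = 40
        for s in range(n_seeds):
            cfg = CohortConfig(seed=s, metric_distributions=flat,
                               tau_area_sppb=0.0, tau_area_gait_speed=0.0,
                               spearman_length_walking_p=0.0,
                               age_area_coupling=0.0, frailty_coupling=0.0)
            table, _ = generate_cohort(cfg)
            rep = reproduce_paper_statistics(table)
            if abs(rep.correlations["spearman_age_area"][0]) < 0.3:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_frailty_bands(self, default_cohort):
        _, table, _ = default_cohort
        rep = reproduce_paper_statistics(table)
        assert rep.frailty["n"] == {"1&2": 20, "3": 10, "4": 4}
        assert 0 <= rep.frailty["p"] <= 1
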