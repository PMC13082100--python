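"""Enrichment statistics against exact enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from scdisp.enrichment import (
    fisher_enrichment,
    group_compare,
    set_enrichment,
    sliding_window_proportion,
    spearman,
)

# ---------------------------------------------------------------------------
# sliding windows


def _ranking(g):
    return pd.Series(np.arange(1, g + 1, dtype=float),
                     index=[f"g{i}" for i in range(g)])


def test_window_full_set_gives_proportion_one():
    ranking = _ranking(50)
    prof = sliding_window_proportion(ranking, set(ranking.index), 10, 5,
                                     n_resamples=10, seed=0)
    assert (prof["proportion"] == 1.0).all()
    assert (prof["band_low"] == 1.0).all()
    assert (prof["band_high"] == 1.0).all()


def test_window_counts_members():
    ranking = _ranking(20)
    members = {"g0", "g1", "g5"}
    prof = sliding_window_proportion(ranking, members, window=10, step=10,
                                     n_resamples=5, seed=0)
    assert prof["proportion"].iloc[0] == pytest.approx(3 / 10)
    assert prof["proportion"].iloc[1] == pytest.approx(0.0)


def test_tiling_windows_mean_equals_set_fraction(rng):
    g, w = 200, 20
    ranking = _ranking(g)
    members = set(rng.choice(list(ranking.index), size=37, replace=False))
    prof = sliding_window_proportion(ranking, members, window=w, step=w,
                                     n_resamples=5, seed=1)
    assert prof["proportion"].mean() == pytest.approx(len(members) / g)


def test_window_band_covers_random_set(rng):
    g = 1000
    ranking = _ranking(g)
    members = set(rng.choice(list(ranking.index), size=200, replace=False))
    prof = sliding_window_proportion(ranking, members, window=100, step=25,
                                     n_resamples=50, seed=2)
    frac = len(members) / g
    covered = ((prof["band_low"] <= frac) & (frac <= prof["band_high"])).mean()
    assert covered >= 0.9


def test_window_validation():
    ranking = _ranking(10)
    with pytest.raises(ValueError):
        sliding_window_proportion(ranking, set(), 0, 1)
    with pytest.raises(ValueError):
        sliding_window_proportion(ranking, {"not_ranked"}, 5, 1)


# ---------------------------------------------------------------------------
# Fisher / hypergeometric


def test_fisher_sample_odds_ratio_arithmetic():
    universe = {f"g{i}" for i in range(500)}
    genes = sorted(universe)
    bin_set = set(genes[:100])           # a+b = 100
    target = set(genes[:10]) | set(genes[100:200])  # a=10, c=100
    res = fisher_enrichment(bin_set, target, universe)
    a, b = res.table[0]
    c, d = res.table[1]
    assert (a, b, c, d) == (10, 90, 100, 300)
    assert res.odds_ratio == pytest.approx((10 * 300) / (90 * 100))
    assert res.ci_low < res.odds_ratio < res.ci_high


def _fisher_bruteforce_p(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("table", [(3, 7, 5, 5), (0, 10, 10, 10), (8, 2, 1, 9),
                                   (5, 5, 5, 5), (1, 0, 0, 1)])
def test_fisher_p_matches_enumeration(table):
    a, b, c, d = table
    genes = [f"g{i}" for i in range(a + b + c + d)]
    universe = set(genes)
    bin_set = set(genes[:a + b])
    target = set(genes[:a]) | set(genes[a + b:a + b + c])
    res = fisher_enrichment(bin_set, target, universe)
    assert res.p == pytest.approx(_fisher_bruteforce_p(a, b, c, d), rel=1e-9)


def test_fisher_zero_cell_ci_finite():
    genes = [f"g{i}" for i in range(40)]
    res = fisher_enrichment(set(genes[:10]), set(genes[10:20]), set(genes))
    assert res.table[0, 0] == 0
    assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)
    assert 0 <= res.p <= 1


def test_fisher_empty_universe_rejected():
    with pytest.raises(ValueError):
        fisher_enrichment(set(), set(), set())


def _hypergeom_upper_tail(N, K, n, k):
    return sum(math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
               for i in range(k, min(K, n) + 1))


def test_set_enrichment_exact_hypergeometric():
    genes = [f"g{i}" for i in range(100)]
    background = set(genes)
    target_set = set(genes[:20])            # K = 20
    query = set(genes[:5]) | set(genes[50:55])  # n = 10, overlap k = 5
    res = set_enrichment(query, {"S": target_set}, background)
    assert res.loc["S", "overlap"] == 5
    expected = _hypergeom_upper_tail(100, 20, 10, 5)  # = 0.025464...
    assert res.loc["S", "p"] == pytest.approx(expected, rel=1e-9)


def test_set_enrichment_disjoint_and_full():
    genes = [f"g{i}" for i in range(50)]
    background = set(genes)
    coll = {"disjoint": set(genes[40:]), "exact": set(genes[:10])}
    res = set_enrichment(set(genes[:10]), coll, background)
    assert res.loc["disjoint", "overlap"] == 0
    assert res.loc["disjoint", "p"] == pytest.approx(1.0)
    assert res["p"].idxmin() == "exact"


def test_set_enrichment_empty_query():
    res = set_enrichment(set(), {"S": {"a"}}, {"a", "b"})
    assert res.empty


def test_set_enrichment_requires_query_in_background():
    with pytest.raises(ValueError):
        set_enrichment({"x"}, {"S": {"a"}}, {"a"})


# ---------------------------------------------------------------------------
# two-group tests and correlation


def test_mwu_exact_small_example():
    vals = pd.Series({"a1": 1.0, "a2": 2.0, "a3": 3.0,
                      "b1": 4.0, "b2": 5.0, "b3": 6.0})
    stat, p = group_compare(vals, {"a1", "a2", "a3"}, {"b1", "b2", "b3"})
    assert stat == 0.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3) orderings as extreme


def test_group_compare_identical_groups():
    vals = pd.Series({f"x{i}": 1.0 for i in range(10)})
    _, p = group_compare(vals, {f"x{i}" for i in range(5)},
                         {f"x{i}" for i in range(5, 10)})
    assert p == 1.0
    _, p_ks = group_compare(vals, {f"x{i}" for i in range(5)},
                            {f"x{i}" for i in range(5, 10)}, test="ks")
    assert p_ks == 1.0


def test_ks_identical_samples(rng):
    v = rng.normal(size=20)
    vals = pd.Series(np.concatenate([v, v]),
                     index=[f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)])
    stat, p = group_compare(vals, {f"a{i}" for i in range(20)},
                            {f"b{i}" for i in range(20)}, test="ks")
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_spearman_examples():
    rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 400])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)
    rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert rho == pytest.approx(0.8)
    rho, p = spearman([1.0, 1.0, 1.0], [1, 2, 3])
    assert math.isnan(rho)
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])
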