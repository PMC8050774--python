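"""Hypergeometric ORA, permutation GSEA, and category summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest

from silaf import (
    CategoryAnnotation,
    GeneSet,
    category_boxplot_summary,
    enrichment_score,
    gsea,
    hypergeom_upper_tail,
    ora,
)


def _ids(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


def exact_upper_tail(k, M, K, N):
    """Brute-force hypergeometric tail by enumeration with binomials."""
    total = math.comb(M, N)
    return sum(math.comb(K, x) * math.comb(M - K, N - x)
               for x in range(k, min(K, N) + 1)) / total


class TestOra:
    def test_worked_example(self):
        # background 20, set of 4, foreground of 5 with 3 hits:
        # [C(4,3)C(16,2) + C(4,4)C(16,1)] / C(20,5) = 496/15504
        bg = set(_ids("g", 20))
        fg = {"g0", "g1", "g2", "g10", "g11"}
        s = GeneSet("S", "", frozenset({"g0", "g1", "g2", "g3"}))
        res = ora(fg, bg, [s])
        assert res.loc["S", "p"] == pytest.approx(496 / 15504, rel=1e-12)
        assert res.loc["S", "n_hits"] == 3

    def test_disjoint_set_with_zero_min_overlap(self):
        bg = set(_ids("g", 10))
        fg = {"g0", "g1"}
        s = GeneSet("S", "", frozenset({"g8", "g9"}))
        res = ora(fg, bg, [s], min_overlap=0)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_foreground_equals_background_gives_p_one(self):
        bg = set(_ids("g", 12))
        sets = [GeneSet("S", "", frozenset({"g0", "g1", "g2", "g3"}))]
        res = ora(bg, bg, sets)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_under_min_overlap_reported_untested(self):
        bg = set(_ids("g", 10))
        s = GeneSet("S", "", frozenset({"g0"}))
        res = ora({"g0", "g5"}, bg, [s], min_overlap=3)
        assert not res.loc["S", "tested"]
        assert np.isnan(res.loc["S", "p"])

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            ora(set(), {"a"}, [])
        with pytest.raises(ValueError, match="subset"):
            ora({"x"}, {"a"}, [])

    def test_matches_exact_enumeration_for_all_small_backgrounds(self):
        """For every background size <= 25 and a sweep of set/foreground/hit
        configurations the hypergeometric tail equals full enumeration."""
        for M in range(2, 26):
            for K in range(1, M + 1, 3):
                for N in range(1, M + 1, 3):
                    for k in range(0, min(K, N) + 1):
                        assert hypergeom_upper_tail(k, M, K, N) == pytest.approx(
                            exact_upper_tail(k, M, K, N), rel=1e-10), (k, M, K, N)


def _brute_force_es(ranked_ids, weights, members):
    """O(N) running-sum reference: independent of the position-based path."""
    hits = np.array([g in members for g in ranked_ids])
    w = np.where(hits, np.abs(weights), 0.0)
    wsum = w.sum()
    if wsum == 0:
        w = hits.astype(float)
        wsum = w.sum()
    n_miss = (~hits).sum()
    running = np.cumsum(np.where(hits, w / wsum, -1.0 / n_miss if n_miss else 0.0))
    return float(running[np.argmax(np.abs(running))])


class TestGsea:
    def test_position_formula_agrees_with_running_sum_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            ids = _ids("g", n)
            fc = np.sort(rng.normal(size=n))[::-1]
            members = set(rng.choice(ids, size=int(rng.integers(2, n // 2 + 2)),
                                     replace=False))
            es, _ = enrichment_score(ids, np.abs(fc), members)
            assert es == pytest.approx(_brute_force_es(ids, fc, members), abs=1e-12)

    def test_top_k_set_is_extremal(self):
        rng = np.random.default_rng(1)
        n, k = 100, 10
        ranked = {f"g{i}": fc for i, fc in
                  enumerate(np.sort(rng.normal(1, 1, size=n))[::-1])}
        top = GeneSet("top", "", frozenset(list(ranked)[:k]))
        others = [GeneSet(f"r{j}", "", frozenset(
            np.random.default_rng(j).choice(list(ranked), size=k, replace=False)))
            for j in range(10)]
        res = gsea(ranked, [top] + others, n_perm=100, seed=0)
        assert res.loc["top", "es"] > 0
        assert res.loc["top", "es"] == res["es"].max()

    def test_unweighted_reduces_to_classic_ks_statistic(self):
        """With all fold changes equal and w = 0 the score is the classic
        unweighted KS running statistic; a uniformly spread set scores low."""
        n = 120
        ids = [f"g{i:03d}" for i in range(n)]  # zero-padded: rank ties keep order
        ranked = [(g, 1.0) for g in ids]
        spread = frozenset(ids[::12])  # every 12th gene: maximally uniform
        res = gsea(ranked, [GeneSet("spread", "", spread)], n_perm=100, seed=0,
                   weight_exponent=0.0)
        es_direct = _brute_force_es(ids, np.ones(n), spread)
        assert res.loc["spread", "es"] == pytest.approx(es_direct, abs=1e-12)
        assert abs(res.loc["spread", "es"]) < 0.15

    def test_es_invariant_to_monotone_rescaling_when_unweighted(self):
        rng = np.random.default_rng(2)
        fc = np.sort(rng.normal(size=60))[::-1]
        ids = _ids("g", 60)
        members = frozenset(rng.choice(ids, size=12, replace=False))
        sets = [GeneSet("S", "", members)]
        r1 = gsea(list(zip(ids, fc)), sets, n_perm=100, seed=3, weight_exponent=0.0)
        r2 = gsea(list(zip(ids, 5 * fc + 100)), sets, n_perm=100, seed=3,
                  weight_exponent=0.0)
        assert r1.loc["S", "es"] == pytest.approx(r2.loc["S", "es"], abs=1e-12)

    def test_permutation_p_bounds_and_abs_es_bounded(self):
        rng = np.random.default_rng(5)
        ids = _ids("g", 80)
        fc = rng.normal(size=80)
        sets = [GeneSet(f"S{j}", "", frozenset(
            rng.choice(ids, size=10, replace=False))) for j in range(5)]
        res = gsea(list(zip(ids, fc)), sets, n_perm=200, seed=6)
        tested = res[res["tested"]]
        assert ((tested["p"] >= 1 / 201) & (tested["p"] <= 1.0)).all()
        assert (tested["es"].abs() <= 1.0).all()

    def test_small_sets_untested_and_duplicates_rejected(self):
        ids = _ids("g", 30)
        ranked = [(g, 1.0) for g in ids]
        res = gsea(ranked, [GeneSet("tiny", "", frozenset(ids[:2]))],
                   n_perm=100, seed=0)
        assert not res.loc["tiny", "tested"]
        with pytest.raises(ValueError, match="duplicate"):
            gsea(ranked + [("g0", 2.0)], [], n_perm=100, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            gsea(ranked, [], n_perm=10, seed=0)

    def test_designed_down_category_detected(self):
        rng = np.random.default_rng(7)
        ids = _ids("g", 400)
        fc = rng.normal(0, 0.25, size=400)
        fc[:50] = rng.normal(-1.0, 0.25, size=50)
        down = GeneSet("down", "", frozenset(ids[:50]))
        # null sets sample the whole list (a set avoiding the down-regulated
        # genes entirely would be genuinely enriched under label permutation)
        nulls = [GeneSet(f"null{j}", "", frozenset(
            rng.choice(ids, size=50, replace=False))) for j in range(5)]
        res = gsea(list(zip(ids, fc)), [down] + nulls, n_perm=500, seed=8)
        assert res.loc["down", "es"] < 0
        assert res.loc["down", "p_adj"] < 0.05
        assert (res.loc[[f"null{j}" for j in range(5)], "p_adj"] > 0.05).all()


class TestCategoryBoxplots:
    def test_definitional_summary(self):
        ann = CategoryAnnotation({f"p{i}": (False, "cat") for i in range(5)})
        vals = {f"p{i}": v for i, v in enumerate([1, 2, 3, 4, 5])}
        res = category_boxplot_summary(vals, ann)
        row = res.loc["cat"]
        assert row["median"] == 3 and row["q25"] == 2 and row["q75"] == 4
        assert row["whisker_low"] >= 2 - 3 and row["whisker_high"] <= 4 + 3
        # whiskers clip to observed data
        assert row["whisker_low"] == 1 and row["whisker_high"] == 5

    def test_category_identical_to_background_not_systematically_significant(self):
        rng = np.random.default_rng(9)
        pvals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = {f"p{i}": float(r.normal()) for i in range(200)}
            ann = CategoryAnnotation({f"p{i}": (False, "cat") for i in range(30)})
            res = category_boxplot_summary(vals, ann)
            pvals.append(res.loc["cat", "p"])
        assert np.mean(np.array(pvals) < 0.05) <= 0.2
        assert np.median(pvals) > 0.1

    def test_shifted_category_flagged(self):
        rng = np.random.default_rng(10)
        vals = {f"p{i}": float(rng.normal()) for i in range(300)}
        for i in range(40):
            vals[f"p{i}"] -= 1.5
        ann = CategoryAnnotation(
            {f"p{i}": (True, "OXPHOS") for i in range(40)}
            | {f"p{i}": (False, "other") for i in range(40, 80)})
        res = category_boxplot_summary(vals, ann)
        assert res.loc["OXPHOS", "p_adj"] < 0.05
        assert res.loc["other", "p_adj"] > 0.05
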