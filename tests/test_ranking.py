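"""ChIP aggregation, blacklist filtering, top-K selection, and LMC ranking."""
import numpy as np
import pytest

import prc2ageindex as pai
from prc2ageindex.ranking import (
    SelectionConfig,
    aggregate_binding,
    density_filter,
    density_filter_sites,
    filter_blacklist,
    rank_concordance,
    rank_lmcs,
    select_top_k,
    select_top_sites,
)


def _random_track(rng, n=200, lo=0, hi=1_000_000, semantics="fold_change"):
    starts = np.sort(rng.choice(np.arange(lo, hi, 100), n, replace=False))
    ends = starts + rng.integers(1, 99, n)
    if semantics == "fold_change":
        values = rng.uniform(0.0, 8.0, n)
    else:
        values = rng.uniform(1e-6, 1.0, n)
    return pai.SignalTrack({"chr1": (starts, ends, values)}, semantics=semantics)


def _dense_oracle(track, chrom, start, end):
    """Per-base mean computed from the raw interval arrays."""
    arr = np.full(end - start, track.gap_value)
    s, e, v = track.data.get(chrom, (np.array([]), np.array([]), np.array([])))
    for si, ei, vi in zip(s, e, v):
        a, b = max(si, start), min(ei, end)
        if b > a:
            arr[a - start : b - start] = vi
    return arr.mean()


class TestAggregateBinding:
    def test_constant_track(self):
        t = pai.SignalTrack({"chr1": ([100], [500], [2.5])})
        (s,) = aggregate_binding([pai.Region("chr1", 200, 400)], [t])
        assert s.prc2_score == pytest.approx(2.5)

    def test_mean_across_factors(self):
        t1 = pai.SignalTrack({"chr1": ([0], [1000], [1.0])})
        t2 = pai.SignalTrack({"chr1": ([0], [1000], [3.0])})
        (s,) = aggregate_binding([pai.Region("chr1", 0, 1000)], [t1, t2])
        assert s.factor_scores == (1.0, 3.0)
        assert s.prc2_score == pytest.approx(2.0)

    def test_mixed_semantics_is_error(self):
        t1 = pai.SignalTrack({"chr1": ([0], [10], [1.0])}, semantics="fold_change")
        t2 = pai.SignalTrack({"chr1": ([0], [10], [0.5])}, semantics="p_value")
        with pytest.raises(ValueError, match="mixed"):
            aggregate_binding([pai.Region("chr1", 0, 10)], [t1, t2])

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        track = _random_track(rng)
        regions = []
        for _ in range(100):
            s = int(rng.integers(0, 995_000))
            regions.append(pai.Region("chr1", s, s + int(rng.integers(50, 4000))))
        scored = aggregate_binding(regions, [track])
        for r, sc in zip(regions, scored):
            assert sc.prc2_score == pytest.approx(
                _dense_oracle(track, "chr1", r.start, r.end), abs=1e-9
            )

    def test_linearity_in_track(self):
        rng = np.random.default_rng(12)
        track = _random_track(rng)
        regions = [pai.Region("chr1", 1000 * i, 1000 * i + 900) for i in range(50)]
        base = [s.prc2_score for s in aggregate_binding(regions, [track])]
        scaled = [s.prc2_score for s in aggregate_binding(regions, [track.scaled(3.0)])]
        np.testing.assert_allclose(scaled, np.array(base) * 3.0, rtol=1e-12)


class TestFilterBlacklist:
    def test_no_overlap_retained(self):
        kept = filter_blacklist(
            [pai.Region("chr1", 100, 200)], [pai.Region("chr1", 300, 400)]
        )
        assert len(kept) == 1

    def test_contained_overlap_removed(self):
        kept = filter_blacklist(
            [pai.Region("chr1", 100, 200)], [pai.Region("chr1", 150, 160)]
        )
        assert kept == []

    def test_single_base_overlap_removed(self):
        kept = filter_blacklist(
            [pai.Region("chr1", 100, 200)], [pai.Region("chr1", 199, 300)]
        )
        assert kept == []

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(13)
        regions = [
            pai.Region("chr1", int(s), int(s) + int(rng.integers(1, 500)))
            for s in rng.integers(0, 100_000, 200)
        ]
        bl = [
            pai.Region("chr1", int(s), int(s) + int(rng.integers(1, 300)))
            for s in rng.integers(0, 100_000, 50)
        ]
        kept = filter_blacklist(regions, bl)
        expect = [
            r for r in regions if not any(r.overlaps(b) for b in bl)
        ]
        assert [(r.start, r.end) for r in kept] == [(r.start, r.end) for r in expect]


def _scored(scores, semantics="fold_change"):
    regions = [
        pai.ScoredRegion("chr1", 1000 * i, 1000 * i + 500, prc2_score=float(s))
        for i, s in enumerate(scores)
    ]
    return aggregate_binding_like(regions, semantics)


def aggregate_binding_like(regions, semantics):
    # assign ranks the way aggregate_binding does, without tracks
    scores = np.array([r.prc2_score for r in regions])
    key = -scores if semantics == "fold_change" else scores
    order = sorted(range(len(regions)), key=lambda i: (key[i], regions[i].start))
    for rank, i in enumerate(order, start=1):
        regions[i].rank = rank
    return regions


class TestSelectTopK:
    def test_default_k_is_1000(self):
        assert SelectionConfig().k == 1000

    def test_forced_ordering(self):
        hp = select_top_k(_scored([5, 3, 9]), SelectionConfig(k=2))
        assert [r.prc2_score for r in hp.regions] == [9, 5]

    def test_p_value_semantics_selects_lowest(self):
        hp = select_top_k(
            _scored([0.5, 0.01, 0.2], semantics="p_value"),
            SelectionConfig(k=2, semantics="p_value"),
        )
        assert [r.prc2_score for r in hp.regions] == [0.01, 0.2]

    def test_matches_sort_oracle_and_order_invariance(self):
        rng = np.random.default_rng(14)
        scores = rng.uniform(0, 10, 500)
        regions = _scored(scores)
        hp = select_top_k(regions, SelectionConfig(k=100))
        expected = set(np.argsort(-scores, kind="stable")[:100] * 1000)
        assert {r.start for r in hp.regions} == expected
        # membership invariant to input order
        shuffled = [regions[i] for i in rng.permutation(len(regions))]
        hp2 = select_top_k(shuffled, SelectionConfig(k=100))
        assert {r.start for r in hp2.regions} == {r.start for r in hp.regions}

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            select_top_k([], SelectionConfig(k=5))

    def test_k_exceeding_n_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="exceeds"):
            hp = select_top_k(_scored([1, 2]), SelectionConfig(k=10))
        assert len(hp) == 2

    def test_members_at_least_as_extreme_as_non_members(self):
        rng = np.random.default_rng(15)
        regions = _scored(rng.uniform(0, 10, 300))
        hp = select_top_k(regions, SelectionConfig(k=50))
        members = {r.start for r in hp.regions}
        min_in = min(r.prc2_score for r in hp.regions)
        max_out = max(r.prc2_score for r in regions if r.start not in members)
        assert min_in >= max_out


class TestRankLmcs:
    def _ref(self, betas, pos=None):
        pos = pos if pos is not None else (np.arange(len(betas)) + 1) * 100
        sites = pai.make_sites("chr1", pos, ".", beta=np.asarray(betas, dtype=float))
        return pai.Methylome("ref", sites, assay="array")

    def test_threshold_rule(self):
        ref = self._ref([0.1, 0.6])
        t = pai.SignalTrack({"chr1": ([0], [1000], [1.0])})
        ranked = rank_lmcs(ref, t, low_threshold=0.3)
        assert list(ranked.table["pos"]) == [100]

    def test_forced_order(self):
        ref = self._ref([0.1, 0.1, 0.1])
        t = pai.SignalTrack(
            {"chr1": ([90, 190, 290], [110, 210, 310], [0.2, 5.0, 1.1])}
        )
        ranked = rank_lmcs(ref, t, low_threshold=0.3)
        by_rank = ranked.table.sort_values("rank")
        assert list(by_rank["pos"]) == [200, 300, 100]

    def test_no_site_below_threshold_is_error(self):
        ref = self._ref([0.9, 0.8])
        t = pai.SignalTrack({"chr1": ([0], [1000], [1.0])})
        with pytest.raises(ValueError, match="threshold"):
            rank_lmcs(ref, t, low_threshold=0.3)

    def test_matches_filter_sort_oracle(self):
        rng = np.random.default_rng(16)
        pos = np.sort(rng.choice(1_000_000, 1000, replace=False))
        betas = rng.random(1000)
        ref = self._ref(betas, pos=pos)
        track = _random_track(rng, n=300)
        ranked = rank_lmcs(ref, track, low_threshold=0.3)
        keep = betas < 0.3
        sig = np.array([track.value_at("chr1", int(p)) for p in pos[keep]])
        assert set(ranked.table["pos"]) == set(pos[keep])
        oracle_order = pos[keep][np.lexsort((pos[keep], -sig))]
        got_order = ranked.table.sort_values("rank")["pos"].to_numpy()
        np.testing.assert_array_equal(got_order, oracle_order)

    def test_select_top_sites_builds_dyad_regions(self):
        ref = self._ref([0.1, 0.2, 0.05])
        t = pai.SignalTrack({"chr1": ([0], [1000], [2.0])})
        ranked = rank_lmcs(ref, t, low_threshold=0.3)
        hp = select_top_sites(ranked, SelectionConfig(k=2))
        assert len(hp) == 2
        assert all(r.end - r.start == 2 for r in hp.regions)


class TestDensityFilter:
    def test_kept_and_dropped(self):
        dense = pai.Region("chr1", 0, 3000)   # 60 CpGs -> 20 /kb
        sparse = pai.Region("chr1", 10_000, 13_000)  # 6 CpGs -> 2 /kb
        cpgs = {"chr1": np.concatenate([np.arange(60) * 50, 10_000 + np.arange(6) * 500])}
        kept = density_filter([dense, sparse], cpgs, min_cpgs_per_kb=10)
        assert kept == [dense]

    def test_matches_count_length_oracle(self):
        rng = np.random.default_rng(17)
        cpgs = {"chr1": np.sort(rng.choice(1_000_000, 20_000, replace=False))}
        regions = [
            pai.Region("chr1", int(s), int(s) + int(rng.integers(500, 5000)))
            for s in rng.integers(0, 990_000, 100)
        ]
        kept = density_filter(regions, cpgs, min_cpgs_per_kb=15)
        p = cpgs["chr1"]
        expect = [
            r
            for r in regions
            if ((p >= r.start) & (p < r.end)).sum() / (r.length / 1000) >= 15
        ]
        assert [(r.start, r.end) for r in kept] == [(r.start, r.end) for r in expect]

    def test_site_filter_restricts_to_dense_neighbourhoods(self):
        dense_pos = np.arange(100) * 10          # 100 CpGs over 1 kb
        sparse_pos = 50_000 + np.arange(5) * 400
        cpgs = {"chr1": np.concatenate([dense_pos, sparse_pos])}
        betas = np.full(105, 0.1)
        sites = pai.make_sites("chr1", cpgs["chr1"], ".", beta=betas)
        ref = pai.Methylome("ref", sites, assay="array")
        t = pai.SignalTrack({"chr1": ([0], [100_000], [1.0])})
        ranked = rank_lmcs(ref, t, low_threshold=0.3)
        filtered = density_filter_sites(ranked, cpgs, min_cpgs_per_kb=10)
        assert set(filtered.table["pos"]) <= set(dense_pos)
        assert len(filtered.table) > 50


class TestRankConcordance:
    def _set(self, scores, offset=0):
        regions = aggregate_binding_like(
            [
                pai.ScoredRegion(
                    "chr1", 1000 * i + offset, 1000 * i + 500 + offset,
                    prc2_score=float(s),
                )
                for i, s in enumerate(scores)
            ],
            "fold_change",
        )
        return select_top_k(regions, SelectionConfig(k=len(scores)))

    def test_identity(self):
        a = self._set([3.0, 1.0, 2.0])
        res = rank_concordance(a, a)
        assert res.overlap_fraction == 1.0
        assert res.rank_correlation == pytest.approx(1.0)

    def test_disjoint(self):
        a = self._set([3.0, 1.0])
        b = self._set([3.0, 1.0], offset=500_000)
        assert rank_concordance(a, b).overlap_fraction == 0.0

    def test_perturbed_scores_match_all_pairs_oracle(self):
        rng = np.random.default_rng(18)
        scores = rng.uniform(0, 10, 100)
        a = self._set(scores)
        b = self._set(scores + rng.normal(0, 0.5, 100))
        res = rank_concordance(a, b)
        a_regions = a.regions
        b_regions = b.regions
        frac = np.mean(
            [any(r.overlaps(s) for s in b_regions) for r in a_regions]
        )
        assert res.overlap_fraction == pytest.approx(frac)
        assert res.rank_correlation > 0.9


def test_planted_targets_dominate_top_k(small_layout, small_hp):
    truth = small_layout.target_regions()
    hits = [any(r.overlaps(t) for t in truth) for r in small_hp.regions]
    assert np.mean(hits) >= 0.9
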