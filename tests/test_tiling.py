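"""Fixed tiling, adjacency, AD/BC distances, merge/reposition and the greedy pass."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adaptile.tiling import (
    PairDistances,
    best_window,
    compute_pair_distances,
    filter_regions_by_cpg,
    find_adjacent_pairs,
    make_fixed_tiles,
    map_cpg_to_regions,
    merge_or_reposition,
    merging_consecutive_regions,
)

from conftest import brute_best_window, positions_matrix, reference_greedy_pass


def regions_df(spans, chrom="chr1", provenance="fixed"):
    return pd.DataFrame({
        "chrom": chrom,
        "start": [s for s, _ in spans],
        "end": [e for _, e in spans],
        "id": [f"{chrom}:{s}-{e}" for s, e in spans],
        "provenance": provenance,
        "source": [f"{chrom}:{s}-{e}" for s, e in spans],
    })


class TestMakeFixedTiles:
    def test_empty_windows_absent(self):
        m = positions_matrix([100, 2500])
        tiles = make_fixed_tiles(m, 1000, 1000)
        assert list(zip(tiles["start"], tiles["end"])) == [(1, 1000), (2001, 3000)]

    def test_min_cpg_threshold(self):
        m = positions_matrix([100, 150, 2500])
        tiles = make_fixed_tiles(m, 1000, 1000, min_cpg=2)
        assert list(zip(tiles["start"], tiles["end"])) == [(1, 1000)]

    def test_empty_matrix_gives_no_tiles(self):
        m = positions_matrix([])
        assert len(make_fixed_tiles(m, 1000)) == 0

    def test_bad_win_size_rejected(self):
        with pytest.raises(ValueError):
            make_fixed_tiles(positions_matrix([10]), 0)


class TestMapCpgToRegions:
    def test_inclusive_boundaries(self):
        m = positions_matrix([1, 500, 1000, 1001])
        cmap = map_cpg_to_regions(m, regions_df([(1, 1000)]))
        assert cmap.n_cpg("chr1:1-1000") == 3

    def test_empty_region_present_with_zero_count(self):
        m = positions_matrix([5000])
        cmap = map_cpg_to_regions(m, regions_df([(1, 1000)]))
        assert cmap.n_cpg("chr1:1-1000") == 0

    def test_boundary_site_assigned_to_left_tile_only(self):
        m = positions_matrix([1000])
        cmap = map_cpg_to_regions(m, regions_df([(1, 1000), (1001, 2000)]))
        assert cmap.n_cpg("chr1:1-1000") == 1
        assert cmap.n_cpg("chr1:1001-2000") == 0


class TestFindAdjacentPairs:
    def test_adjacency_is_exact_contiguity(self):
        pairs = find_adjacent_pairs(regions_df([(1, 1000), (1001, 2000), (3001, 4000)]))
        assert pairs == [(0, 1)]

    def test_no_pairs_across_chromosomes(self):
        r = pd.concat([regions_df([(1, 1000)], chrom="chr1"),
                       regions_df([(1001, 2000)], chrom="chr2")], ignore_index=True)
        assert find_adjacent_pairs(r) == []

    def test_single_tile_no_pairs(self):
        assert find_adjacent_pairs(regions_df([(1, 1000)])) == []

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            find_adjacent_pairs(regions_df([(1, 1000), (900, 1900)]))


class TestPairDistances:
    def test_distances_from_anchor_cpgs(self):
        m = positions_matrix([1900, 1950, 2050, 2100])
        r = regions_df([(1001, 2000), (2001, 3000)])
        d = compute_pair_distances(tuple(r["id"]), map_cpg_to_regions(m, r), m)
        assert (d.A, d.B, d.C, d.D) == (1900, 1950, 2050, 2100)
        assert (d.AD, d.BC) == (200, 100)

    def test_single_cpg_tiles(self):
        m = positions_matrix([10, 1500])
        r = regions_df([(1, 1000), (1001, 2000)])
        d = compute_pair_distances(tuple(r["id"]), map_cpg_to_regions(m, r), m)
        assert d.A == d.B == 10 and d.C == d.D == 1500
        assert d.AD == d.BC == 1490

    def test_asymmetric_pair(self):
        m = positions_matrix([800, 950, 1100, 1850, 1900, 1950])
        r = regions_df([(1, 1000), (1001, 2000)])
        d = compute_pair_distances(tuple(r["id"]), map_cpg_to_regions(m, r), m)
        assert (d.AD, d.BC) == (1150, 150)

    def test_empty_tile_rejected(self):
        m = positions_matrix([100])
        r = regions_df([(1, 1000), (1001, 2000)])
        with pytest.raises(ValueError, match="no CpGs"):
            compute_pair_distances(tuple(r["id"]), map_cpg_to_regions(m, r), m)

    def test_anchor_order_invariant_enforced(self):
        with pytest.raises(ValueError):
            PairDistances(A=100, B=200, C=150, D=300)


class TestBestWindow:
    def test_downstream_tie_break(self):
        cpgs = np.array([800, 950, 1100, 1850, 1900, 1950])
        s, e, count = best_window(cpgs, (800, 1950), 1000)
        assert (s, e, count) == (951, 1950, 4)

    def test_window_keeping_both_cpgs_wins(self):
        s, e, count = best_window(np.array([10, 20]), (10, 26), 15)
        assert (s, e, count) == (10, 24, 2)

    def test_all_cpgs_in_one_window(self):
        s, e, count = best_window(np.array([100, 105, 110]), (100, 1500), 1000)
        assert count == 3

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            best_window(np.array([10, 20]), (10, 20), 100)

    @settings(max_examples=150, derandomize=True)
    @given(st.data())
    def test_matches_one_bp_sliding_oracle(self, data):
        """CpG-anchored candidate enumeration == exhaustive 1-bp scan."""
        L = data.draw(st.sampled_from([50, 100, 200]))
        A = data.draw(st.integers(1, 500))
        width = data.draw(st.integers(L, 4 * L))
        D = A + width
        n = data.draw(st.integers(2, 20))
        inner = data.draw(st.lists(st.integers(A + 1, D - 1), min_size=max(0, n - 2),
                                   max_size=n - 2, unique=True))
        cpgs = np.unique(np.array([A, D] + inner))
        s, e, count = best_window(cpgs, (A, D), L)
        s_ref, count_ref = brute_best_window(cpgs.tolist(), A, D, L)
        assert (s, count) == (s_ref, count_ref)


def run_pair(left, right, L):
    """Apply merge_or_reposition to the contiguous tiles [1, L] and [L+1, .].

    Left CpGs must lie in [1, L]; the right tile is [L+1, max(2L, last CpG)]
    (a wider-than-L right tile only stretches the arena, not the rule).
    """
    assert max(left) <= L and min(right) > L
    r = regions_df([(1, L), (L + 1, max(2 * L, max(right)))])
    m = positions_matrix(sorted(left) + sorted(right))
    cmap = map_cpg_to_regions(m, r)
    pair = tuple(r["id"])
    dist = compute_pair_distances(pair, cmap, m)
    return merge_or_reposition(pair, dist, L, cmap, m, r)


# ~30 hand-derived boundary cases: AD in {L-1, L, L+1}, BC in {L-1, L},
# single-CpG tiles, count ties.  Expected spans follow from the rules
# (merge iff AD < L; else reposition iff BC < L, most-downstream tie-break);
# None means the pair is left unchanged.
BOUNDARY_CASES = [
    # --- merges: AD < L ---
    ([50, 60], [110, 149], 100, (50, 149, "merged")),          # AD = L-1
    ([10], [108], 100, (10, 108, "merged")),                   # singles, AD = 98
    ([99, 100], [101, 198], 100, (99, 198, "merged")),         # AD = L-1, touching
    ([100], [101], 100, (100, 101, "merged")),                 # AD = 1
    ([90], [110], 100, (90, 110, "merged")),                   # AD = 20
    ([10], [105], 100, (10, 105, "merged")),                   # AD = 95
    ([50], [149], 100, (50, 149, "merged")),                   # AD = L-1, singles
    ([100, 150, 199], [220, 298], 200, (100, 298, "merged")),  # L=200, AD = 198
    ([901, 950, 1000], [1001, 1050], 1000, (901, 1050, "merged")),
    ([900, 950], [1050, 1100], 1000, (900, 1100, "merged")),
    ([5], [101, 102, 103], 100, (5, 103, "merged")),           # AD = 98
    ([95, 96, 97, 98, 99], [190], 100, (95, 190, "merged")),   # AD = 95
    # --- AD == L exactly: merge does not fire; repositioning test applies ---
    ([50], [150], 100, None),                                  # BC = L too
    ([40], [140], 100, None),
    ([1], [101], 100, None),
    ([50, 99], [102, 150], 100, (51, 150, "repositioned")),    # BC = 3, 3-3 tie
    ([50, 60], [149, 150], 100, (51, 150, "repositioned")),    # BC = 89, 3-3 tie
    ([95, 96, 97, 98, 99], [195], 100, (96, 195, "repositioned")),  # BC = 96, 5-5 tie
    # --- AD == L+1 ---
    ([50, 99], [103, 151], 100, (52, 151, "repositioned")),    # BC = 4, 3-3 tie
    ([50], [151], 100, None),                                  # BC = L+1
    ([5], [103, 104, 105, 106], 100, (7, 106, "repositioned")),  # AD = 101, BC = 98
    # --- BC boundary with AD large ---
    ([10, 20], [119, 400], 100, (20, 119, "repositioned")),    # BC = L-1
    ([10, 20], [120, 400], 100, None),                         # BC = L exactly
    ([10, 20], [119, 130], 100, (31, 130, "repositioned")),    # BC = L-1, 2-2 tie
    # --- repositioning tie-breaks ---
    ([1, 2, 3], [102, 103, 104], 100, (5, 104, "repositioned")),  # AD=103, BC=99, 3-3 tie
    ([1, 2, 3], [150, 151, 152], 100, None),                   # AD=151, BC=147
    ([1, 99], [101, 199], 100, (100, 199, "repositioned")),    # BC = 2, max count 2
    ([800, 950], [1100, 1850, 1900, 1950], 1000, (951, 1950, "repositioned")),
    # --- plain no-ops: both distances >= L ---
    ([10, 20], [1500, 1600, 1700], 1000, None),
    ([5], [200], 100, None),
    ([1], [250], 100, None),
    ([95, 96, 97, 98, 99], [260], 100, None),                  # AD = 165, BC = 161
]


@pytest.mark.parametrize("left,right,L,expected", BOUNDARY_CASES)
def test_merge_or_reposition_boundary_rules(left, right, L, expected):
    result = run_pair(left, right, L)
    if expected is None:
        assert len(result) == 2
        assert [r["provenance"] for r in result] == ["fixed", "fixed"]
    else:
        assert len(result) == 1
        got = (result[0]["start"], result[0]["end"], result[0]["provenance"])
        assert got == expected


class TestGreedyPass:
    def test_merged_pair_not_repaired_within_pass(self):
        # tiles 1+2 merge; tile 3 must not pair with the merged result
        m = positions_matrix([950, 1050, 2001, 2900])
        tiles = regions_df([(1, 1000), (1001, 2000), (2001, 3000)])
        out = merging_consecutive_regions(m, tiles, 1000)
        assert out["provenance"].tolist() == ["merged", "fixed"]
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (950, 1050)
        assert out.loc[1, "start"] == 2001

    def test_no_adjacent_pairs_is_identity(self):
        m = positions_matrix([100, 5100])
        tiles = regions_df([(1, 1000), (5001, 6000)])
        out = merging_consecutive_regions(m, tiles, 1000)
        pd.testing.assert_frame_equal(
            out[["chrom", "start", "end"]], tiles[["chrom", "start", "end"]]
        )

    def test_source_records_consumed_tile_ids(self):
        m = positions_matrix([950, 1050])
        tiles = regions_df([(1, 1000), (1001, 2000)])
        out = merging_consecutive_regions(m, tiles, 1000)
        assert out.loc[0, "source"] == "chr1:1-1000,chr1:1001-2000"

    def test_unsorted_or_overlapping_tiles_rejected(self):
        m = positions_matrix([100, 1100])
        bad = regions_df([(1, 1000), (500, 1499)])
        with pytest.raises(ValueError):
            merging_consecutive_regions(m, bad, 1000)

    def test_zero_cpg_tile_rejected(self):
        m = positions_matrix([100])
        tiles = regions_df([(1, 1000), (1001, 2000)])
        with pytest.raises(ValueError, match="without CpGs"):
            merging_consecutive_regions(m, tiles, 1000)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_reference_pass_on_random_landscapes(self, seed):
        """Optimizer output equals a naive reference greedy pass."""
        rng = np.random.default_rng(seed)
        # clustered positions: a few dense clumps plus sparse background
        pos = np.unique(np.concatenate([
            rng.integers(1, 30_000, size=30),
            (rng.integers(1, 28_000, size=3)[:, None] + rng.integers(0, 600, size=(3, 25))).ravel(),
        ]))
        m = positions_matrix(pos.tolist())
        L = 1000
        tiles = make_fixed_tiles(m, L, L)
        out = merging_consecutive_regions(m, tiles, L)

        spans = list(zip(tiles["start"].tolist(), tiles["end"].tolist()))
        cmap = map_cpg_to_regions(m, tiles)
        cpgs = [cmap.positions(rid, m).tolist() for rid in tiles["id"]]
        expected = reference_greedy_pass(spans, cpgs, L)
        got = list(zip(out["start"].tolist(), out["end"].tolist(), out["provenance"].tolist()))
        assert got == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_structural_invariants(self, seed, small_config):
        """Length bound, CpG conservation, density improvement, sortedness."""
        from adaptile.simulate import simulate_dataset

        m, _ = simulate_dataset(small_config(seed))
        L = 1000
        tiles = make_fixed_tiles(m, L, L)
        tile_map = map_cpg_to_regions(m, tiles)
        out = merging_consecutive_regions(m, tiles, L)
        out_map = map_cpg_to_regions(m, out)

        lengths = out["end"] - out["start"] + 1
        assert (lengths <= L).all()
        starts = out["start"].to_numpy()
        ends = out["end"].to_numpy()
        assert (starts[1:] > ends[:-1]).all()  # sorted, non-overlapping (one chrom)

        tile_counts = {rid: tile_map.n_cpg(rid) for rid in tiles["id"]}
        tile_len = dict(zip(tiles["id"], tiles["end"] - tiles["start"] + 1))
        for rec in out.itertuples(index=False):
            if rec.provenance == "fixed":
                continue
            src = rec.source.split(",")
            n = out_map.n_cpg(rec.id)
            if rec.provenance == "merged":
                assert n == tile_counts[src[0]] + tile_counts[src[1]]
            else:
                assert n >= max(tile_counts[src[0]], tile_counts[src[1]])
            density = n / (rec.end - rec.start + 1)
            in_density = max(tile_counts[s] / tile_len[s] for s in src)
            assert density >= in_density - 1e-12

    def test_idempotent_on_own_output(self, small_config):
        from adaptile.simulate import simulate_dataset

        m, _ = simulate_dataset(small_config(3))
        tiles = make_fixed_tiles(m, 1000, 1000)
        once = merging_consecutive_regions(m, tiles, 1000)
        twice = merging_consecutive_regions(m, once, 1000)
        assert ((twice["end"] - twice["start"] + 1) <= 1000).all()
        # merged regions never come apart again
        assert (twice["provenance"] == "merged").sum() >= (once["provenance"] == "merged").sum()


class TestFilterRegionsByCpg:
    def test_strict_inequality(self):
        m = positions_matrix(list(range(10, 60, 10)) + list(range(1010, 1070, 10)))
        regions = regions_df([(1, 1000), (1001, 2000)])  # 5 and 6 CpGs
        cmap = map_cpg_to_regions(m, regions)
        kept, removed = filter_regions_by_cpg(regions, cmap, 5)
        assert kept["id"].tolist() == ["chr1:1001-2000"]
        assert removed == pytest.approx(0.5)

    def test_threshold_zero_keeps_covered_regions(self):
        m = positions_matrix([100])
        regions = regions_df([(1, 1000)])
        kept, removed = filter_regions_by_cpg(regions, map_cpg_to_regions(m, regions), 0)
        assert len(kept) == 1 and removed == 0.0

    def test_empty_region_set(self):
        regions = regions_df([])
        from adaptile.tiling import RegionCpGMap
        kept, removed = filter_regions_by_cpg(regions, RegionCpGMap({}), 5)
        assert len(kept) == 0 and removed == 0.0
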