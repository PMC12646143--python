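"""Fixed tiling and data-adaptive refinement of adjacent tile pairs.

The refinement works on directly adjacent, non-overlapping tile pairs.  For a
pair, let A/B be the first/last sequenced CpG position of the left tile and C/D
the first/last of the right tile, and define the distances ``AD = D - A`` and
``BC = C - B`` (bp, differences of 1-based positions).  With tile size ``L``:

* ``AD < L`` — the CpGs of both tiles are tightly clustered: the pair is merged
  into a single region ``[A, D]`` spanning every CpG of both tiles;
* ``AD >= L`` but ``BC < L`` — the two clusters are separated by a narrow gap:
  the pair is replaced by the fixed-size window of length ``L`` inside the span
  ``[A, D]`` that contains the most CpGs (ties broken toward the most
  downstream, i.e. largest, start);
* otherwise the two tiles are left unchanged.

A single greedy left-to-right pass applies this rule per chromosome; a pair
that was transformed is consumed and its result is not re-paired within the
pass.  Every region the optimizer emits is at most ``L`` bp long, so merged
regions remain comparable with the fixed tiles they replace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from adaptile.io import REGION_COLUMNS, MethylationMatrix, validate_regions

logger = logging.getLogger("adaptile")


@dataclass(frozen=True)
class PairDistances:
    """CpG anchor positions and distances for an adjacent tile pair."""

    A: int  #: first CpG of the left tile
    B: int  #: last CpG of the left tile
    C: int  #: first CpG of the right tile
    D: int  #: last CpG of the right tile

    def __post_init__(self) -> None:
        if not (self.A <= self.B < self.C <= self.D):
            raise ValueError(f"anchors must satisfy A <= B < C <= D, got {self}")

    @property
    def AD(self) -> int:
        """Distance from the left tile's first CpG to the right tile's last."""
        return self.D - self.A

    @property
    def BC(self) -> int:
        """Distance from the left tile's last CpG to the right tile's first."""
        return self.C - self.B


class RegionCpGMap:
    """Assignment of site indices (rows of the matrix) to region ids."""

    def __init__(self, indices: dict[str, np.ndarray]):
        self.indices = {rid: np.asarray(ix, dtype=np.int64) for rid, ix in indices.items()}

    def __contains__(self, rid: str) -> bool:
        return rid in self.indices

    def __getitem__(self, rid: str) -> np.ndarray:
        return self.indices[rid]

    def n_cpg(self, rid: str) -> int:
        return len(self.indices[rid])

    @property
    def counts(self) -> pd.Series:
        return pd.Series({rid: len(ix) for rid, ix in self.indices.items()}, dtype=np.int64)

    def positions(self, rid: str, matrix: MethylationMatrix) -> np.ndarray:
        return matrix.sites["pos"].to_numpy()[self.indices[rid]]


def make_fixed_tiles(
    matrix: MethylationMatrix,
    win_size: int = 1000,
    step_size: int | None = None,
    min_cpg: int = 1,
) -> pd.DataFrame:
    """Lay a fixed tiling grid over the sequenced CpGs.

    Candidate windows are ``[1 + k*step, 1 + k*step + win_size - 1]`` anchored
    at coordinate 1 on each chromosome; only windows containing at least
    ``max(1, min_cpg)`` sequenced CpGs are returned (empty tiles would leave
    the pair distances undefined downstream).
    """
    if win_size < 1:
        raise ValueError("win_size must be >= 1")
    if step_size is None:
        step_size = win_size
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    if step_size > win_size:
        logger.info("gapped tiling: step_size %d > win_size %d", step_size, win_size)
    min_cpg = max(1, min_cpg)

    rows = []
    for chrom, lo, hi in matrix.chrom_blocks():
        pos = matrix.sites["pos"].to_numpy()[lo:hi]
        k_max = (pos[-1] - 1) // step_size
        starts = 1 + step_size * np.arange(k_max + 1, dtype=np.int64)
        ends = starts + win_size - 1
        counts = np.searchsorted(pos, ends, side="right") - np.searchsorted(pos, starts, side="left")
        keep = counts >= min_cpg
        for s, e in zip(starts[keep], ends[keep]):
            rows.append((chrom, int(s), int(e)))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    regions["id"] = [f"{c}:{s}-{e}" for c, s, e in rows]
    regions["provenance"] = "fixed"
    regions["source"] = regions["id"]
    return regions


def map_cpg_to_regions(matrix: MethylationMatrix, regions: pd.DataFrame) -> RegionCpGMap:
    """Map each region to the matrix row indices of the CpGs it contains
    (``region.start <= pos <= region.end``, both inclusive).

    Sites outside every region stay unassigned.  If input regions overlap, a
    site may legitimately map to several of them.
    """
    blocks = {chrom: (lo, hi) for chrom, lo, hi in matrix.chrom_blocks()}
    all_pos = matrix.sites["pos"].to_numpy()
    indices: dict[str, np.ndarray] = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        if chrom not in blocks:
            for rid in sub["id"]:
                indices[rid] = np.empty(0, dtype=np.int64)
            continue
        lo, hi = blocks[chrom]
        pos = all_pos[lo:hi]
        first = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        last = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        for rid, f, l in zip(sub["id"], first, last):
            indices[rid] = np.arange(lo + f, lo + l, dtype=np.int64)
    return RegionCpGMap(indices)


def find_adjacent_pairs(regions: pd.DataFrame) -> list[tuple[int, int]]:
    """Indices (row positions) of directly adjacent tile pairs.

    A pair is two same-chromosome tiles with ``right.start == left.end + 1``.
    Input must be sorted by (chrom, start) and non-overlapping.
    """
    validate_regions(regions)
    pairs: list[tuple[int, int]] = []
    chrom = regions["chrom"].to_numpy()
    start = regions["start"].to_numpy()
    end = regions["end"].to_numpy()
    for i in range(len(regions) - 1):
        if chrom[i + 1] != chrom[i]:
            continue
        if start[i + 1] <= start[i] or start[i + 1] <= end[i]:
            raise ValueError(
                f"regions must be sorted and non-overlapping "
                f"({regions['id'].iat[i]} vs {regions['id'].iat[i + 1]})"
            )
        if start[i + 1] == end[i] + 1:
            pairs.append((i, i + 1))
    return pairs


def compute_pair_distances(
    pair: tuple[str, str],
    cpg_map: RegionCpGMap,
    matrix: MethylationMatrix,
) -> PairDistances:
    """AD/BC anchor distances for an adjacent pair of region ids."""
    left_id, right_id = pair
    left = cpg_map.positions(left_id, matrix)
    right = cpg_map.positions(right_id, matrix)
    if len(left) == 0 or len(right) == 0:
        raise ValueError(f"pair ({left_id}, {right_id}) has a tile with no CpGs")
    return PairDistances(int(left[0]), int(left[-1]), int(right[0]), int(right[-1]))


def best_window(span_cpgs: np.ndarray, span: tuple[int, int], L: int) -> tuple[int, int, int]:
    """The length-``L`` window inside ``span = [A, D]`` with the most CpGs.

    Candidate starts run over ``A <= s <= D - L + 1``; among count maxima the
    largest (most downstream) start wins.  Returns ``(start, end, count)``.

    Only starts at CpG positions plus the rightmost admissible start need to be
    examined: the count as a function of ``s`` only strictly drops one past a
    CpG position, so the most downstream maximiser is either a CpG position or
    ``D - L + 1``.  (Equivalence with a 1-bp sliding scan is asserted in the
    test suite.)
    """
    A, D = span
    if D - A < L:
        raise ValueError(f"span [{A}, {D}] shorter than window length {L}")
    pos = np.asarray(span_cpgs, dtype=np.int64)
    if pos.size == 0:
        raise ValueError("span contains no CpGs")
    if pos.min() < A or pos.max() > D:
        raise ValueError("span_cpgs must lie within the span")
    s_max = D - L + 1
    cand = np.unique(np.clip(np.append(pos, s_max), A, s_max))
    counts = np.searchsorted(pos, cand + L - 1, side="right") - np.searchsorted(pos, cand, side="left")
    best = counts.max()
    s = int(cand[counts == best].max())
    return s, s + L - 1, int(best)


def merge_or_reposition(
    pair: tuple[str, str],
    dist: PairDistances,
    L: int,
    cpg_map: RegionCpGMap,
    matrix: MethylationMatrix,
    regions: pd.DataFrame | None = None,
) -> list[dict]:
    """Apply the merge / reposition / leave-unchanged rule to one pair.

    Returns one region record when the pair is transformed and two (the inputs,
    untouched) when it is not.  The ``AD == L`` boundary falls through to the
    repositioning test, matching the strict ``AD < L`` merge rule.
    """
    left_id, right_id = pair
    chrom = None
    if regions is not None:
        row = regions.loc[regions["id"] == left_id]
        chrom = row["chrom"].iat[0] if len(row) else None

    def record(start: int, end: int, provenance: str) -> dict:
        return {
            "chrom": chrom, "start": start, "end": end,
            "id": f"{chrom}:{start}-{end}" if chrom else f"{start}-{end}",
            "provenance": provenance, "source": f"{left_id},{right_id}",
        }

    if dist.AD < L:
        return [record(dist.A, dist.D, "merged")]
    if dist.BC < L:
        span_cpgs = np.concatenate([
            cpg_map.positions(left_id, matrix),
            cpg_map.positions(right_id, matrix),
        ])
        s, e, _ = best_window(span_cpgs, (dist.A, dist.D), L)
        return [record(s, e, "repositioned")]
    if regions is None:
        raise ValueError("unchanged branch needs the region table to return the inputs")
    keep = regions.loc[regions["id"].isin([left_id, right_id])]
    return keep.to_dict("records")


def merging_consecutive_regions(
    matrix: MethylationMatrix,
    tiles: pd.DataFrame,
    L: int,
    iterate_to_convergence: bool = False,
) -> pd.DataFrame:
    """Refine a sorted, non-overlapping tile set with one greedy pass.

    Walking left to right within each chromosome: when tiles ``i`` and ``i+1``
    are directly adjacent, apply :func:`merge_or_reposition`; if the pair was
    transformed into a single region both tiles are consumed (the result is not
    re-paired within this pass) and the walk continues at ``i + 2``, otherwise
    tile ``i`` is kept and the walk continues at ``i + 1``.

    With ``iterate_to_convergence`` the pass is repeated on its own output
    until a fixpoint (off by default: transformed regions are rarely exactly
    adjacent to their neighbours, so extra passes usually change nothing).
    """
    validate_regions(tiles)
    if len(tiles) == 0:
        return tiles.reindex(columns=REGION_COLUMNS)
    if ((tiles["end"] - tiles["start"] + 1) > L).any():
        raise ValueError(f"input tile longer than tile size L={L}")
    tiles = tiles.reset_index(drop=True)

    cpg_map = map_cpg_to_regions(matrix, tiles)
    zero = [rid for rid in tiles["id"] if cpg_map.n_cpg(rid) == 0]
    if zero:
        raise ValueError(f"tiles without CpGs cannot be optimized: {zero[:5]}")

    adjacent = dict(find_adjacent_pairs(tiles))  # left index -> right index
    chrom = tiles["chrom"].to_numpy()
    out_rows: list[dict] = []
    i = 0
    n = len(tiles)
    while i < n:
        j = adjacent.get(i)
        if j is not None:
            pair = (tiles["id"].iat[i], tiles["id"].iat[j])
            dist = compute_pair_distances(pair, cpg_map, matrix)
            result = merge_or_reposition(pair, dist, L, cpg_map, matrix, tiles)
            if len(result) == 1:
                rec = result[0]
                rec["chrom"] = chrom[i]
                rec["id"] = f"{chrom[i]}:{rec['start']}-{rec['end']}"
                out_rows.append(rec)
                i = j + 1
                continue
        out_rows.append(tiles.iloc[i].to_dict())
        i += 1

    out = pd.DataFrame(out_rows, columns=REGION_COLUMNS)
    out = out.reset_index(drop=True)
    if iterate_to_convergence:
        again = merging_consecutive_regions(matrix, out, L, iterate_to_convergence=False)
        while not again.reset_index(drop=True)[["chrom", "start", "end"]].equals(
            out[["chrom", "start", "end"]]
        ):
            out = again.reset_index(drop=True)
            again = merging_consecutive_regions(matrix, out, L, iterate_to_convergence=False)
    return out


def filter_regions_by_cpg(
    regions: pd.DataFrame,
    cpg_map: RegionCpGMap,
    min_cpg_exclusive: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Keep regions with strictly more than ``min_cpg_exclusive`` CpGs.

    Returns the kept regions and the fraction removed (0.0 on empty input).
    The strict inequality mirrors the usual "> n CpGs" phrasing of
    minimum-information filters.
    """
    if len(regions) == 0:
        return regions.copy(), 0.0
    counts = np.array([cpg_map.n_cpg(rid) for rid in regions["id"]])
    keep = counts > min_cpg_exclusive
    removed = 1.0 - keep.mean()
    return regions.loc[keep].reset_index(drop=True), float(removed)
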