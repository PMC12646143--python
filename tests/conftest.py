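"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the most naive route
(1-bp sliding scans, all-pairs loops, a straightforward re-implementation of
the greedy merge pass) so the package's optimised code paths can be checked
against them without sharing logic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adaptile.io import MethylationMatrix


def make_matrix(
    positions,
    betas: dict[str, list[float]],
    chrom: str = "chr1",
    coverage: int = 10,
    groups: dict[str, str] | None = None,
) -> MethylationMatrix:
    """Build a small single-chromosome matrix from explicit betas.

    ``betas`` maps sample id -> per-site beta list (NaN = missing).
    Coverage is constant except where beta is missing (then 0).
    """
    samples = list(betas)
    beta = np.column_stack([np.asarray(betas[s], dtype=float) for s in samples])
    cov = np.full(beta.shape, coverage, dtype=np.int64)
    cov[np.isnan(beta)] = 0
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=np.int64),
        "strand": ".",
    })
    return MethylationMatrix(sites, samples, beta, cov, groups or {})


def positions_matrix(positions, chrom: str = "chr1") -> MethylationMatrix:
    """Matrix with one sample and constant beta; only positions matter."""
    return make_matrix(positions, {"s1": [0.5] * len(positions)}, chrom=chrom)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_best_window(positions, A: int, D: int, L: int) -> tuple[int, int]:
    """1-bp exhaustive sliding scan; returns (start, count), downstream ties."""
    pos = sorted(positions)
    best_s, best_count = None, -1
    for s in range(A, D - L + 2):
        count = sum(1 for p in pos if s <= p <= s + L - 1)
        if count >= best_count:
            best_s, best_count = s, count
    return best_s, best_count


def brute_overlaps(regions: pd.DataFrame, features: pd.DataFrame,
                   site_pos: dict[str, np.ndarray]) -> set[tuple]:
    """All-pairs overlap scan; returns {(region_id, feature_id, bp, n_cpg)}."""
    out = set()
    for r in regions.itertuples(index=False):
        for f in features.itertuples(index=False):
            if r.chrom != f.chrom:
                continue
            o_start, o_end = max(r.start, f.start), min(r.end, f.end)
            if o_start > o_end:
                continue
            pos = site_pos.get(r.id, np.empty(0))
            n = int(np.sum((pos >= o_start) & (pos <= o_end)))
            out.add((r.id, f.feature_id, o_end - o_start + 1, n))
    return out


def reference_greedy_pass(tile_spans: list[tuple[int, int]],
                          cpgs_by_tile: list[list[int]],
                          L: int) -> list[tuple[int, int, str]]:
    """Plain re-implementation of the single greedy merge/reposition pass on
    one chromosome.  Tiles are (start, end) with their CpG position lists.
    Returns (start, end, provenance) triples."""
    out = []
    i = 0
    while i < len(tile_spans):
        if i + 1 < len(tile_spans) and tile_spans[i + 1][0] == tile_spans[i][1] + 1:
            left, right = cpgs_by_tile[i], cpgs_by_tile[i + 1]
            A, B, C, D = left[0], left[-1], right[0], right[-1]
            if D - A < L:
                out.append((A, D, "merged"))
                i += 2
                continue
            if C - B < L:
                s, _ = brute_best_window(left + right, A, D, L)
                out.append((s, s + L - 1, "repositioned"))
                i += 2
                continue
        out.append((*tile_spans[i], "fixed"))
        i += 1
    return out


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic RRBS dataset at a fixed seed (study conditions)."""
    from adaptile.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator config for many-landscape loops."""
    from adaptile.simulate import SimulationConfig

    def factory(seed: int):
        return SimulationConfig(
            seed=seed, chrom_lengths={"chr1": 150_000}, n_islands=6,
        )

    return factory
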