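"""Readers/writers for the formats the tool touches and the multi-sample matrix.

Internal coordinates are 1-based and fully inclusive ``[start, end]`` everywhere;
conversion to/from BED's 0-based half-open convention happens only at the BED
boundary.  Chromosomes are kept in first-appearance order (no lexical sort is
imposed), with positions ascending within each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("adaptile")

#: columns of a per-sample site table (one sequenced CpG per row)
SITE_COLUMNS = ["chrom", "pos", "strand", "beta", "coverage"]

#: columns of a region table
REGION_COLUMNS = ["chrom", "start", "end", "id", "provenance", "source"]

PROVENANCE_VALUES = frozenset({"fixed", "merged", "repositioned"})


class BismarkParseError(ValueError):
    """Raised when a Bismark coverage file violates the 6-column dialect."""


def _order_chroms(chroms: Iterable[str]) -> list[str]:
    """Unique chromosome names in first-appearance order."""
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    return list(seen)


def sort_sites(table: pd.DataFrame, chrom_order: list[str] | None = None) -> pd.DataFrame:
    """Sort a site table by (chromosome first-appearance order, position)."""
    if chrom_order is None:
        chrom_order = _order_chroms(table["chrom"])
    cat = pd.Categorical(table["chrom"], categories=chrom_order, ordered=True)
    out = table.assign(_c=cat).sort_values(["_c", "pos"], kind="stable")
    return out.drop(columns="_c").reset_index(drop=True)


@dataclass
class MethylationMatrix:
    """Multi-sample CpG-level methylation matrix.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based bp, int) and
        ``strand`` (one of ``+ - .``), sorted by chromosome (first-appearance
        order) then position, with no duplicate (chrom, pos).
    samples
        Ordered sample identifiers; one column of `beta`/`coverage` each.
    beta
        float array of shape (n_sites, n_samples); methylation proportion in
        [0, 1], NaN where the site is missing in that sample.
    coverage
        integer array of the same shape; read counts, 0 exactly where beta
        is missing.
    groups
        Mapping sample id -> group label.
    """

    sites: pd.DataFrame
    samples: list[str]
    beta: np.ndarray
    coverage: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.beta = np.asarray(self.beta, dtype=float)
        self.coverage = np.asarray(self.coverage)
        if self.beta.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.coverage.shape != self.beta.shape:
            raise ValueError("coverage shape does not match beta shape")
        if not self.groups:
            self.groups = {s: "all" for s in self.samples}
        self.validate()

    def validate(self) -> None:
        if len(self.sites) == 0:
            return
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        missing = np.isnan(self.beta)
        if np.any((self.coverage == 0) != missing):
            raise ValueError("beta must be missing exactly where coverage is 0")
        finite = self.beta[~missing]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        for chrom, lo, hi in self.chrom_blocks():
            pos = self.sites["pos"].to_numpy()[lo:hi]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"sites on {chrom} not strictly increasing")
        if set(self.groups) != set(self.samples):
            raise ValueError("groups must map every sample and nothing else")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chrom_order(self) -> list[str]:
        return _order_chroms(self.sites["chrom"])

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chrom, row_start, row_stop) blocks of the site table."""
        chroms = self.sites["chrom"].to_numpy()
        if chroms.size == 0:
            return []
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        bounds = np.concatenate(([0], change, [chroms.size]))
        return [(chroms[bounds[i]], int(bounds[i]), int(bounds[i + 1]))
                for i in range(len(bounds) - 1)]

    def positions(self, chrom: str) -> np.ndarray:
        mask = self.sites["chrom"].to_numpy() == chrom
        return self.sites["pos"].to_numpy()[mask]

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    @property
    def group_labels(self) -> list[str]:
        return _order_chroms(self.groups[s] for s in self.samples)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bismark_coverage(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one Bismark coverage file into a per-sample site table.

    The dialect is 6 tab-separated columns: chrom, start, end, %methylation,
    count methylated, count unmethylated; 1-based with start == end; optionally
    gzip-compressed.  Beta is recomputed from the counts (count_M / total), rows
    with zero total count are dropped, and the output is sorted by
    (chromosome, position).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SITE_COLUMNS)
    except pd.errors.ParserError as exc:  # ragged rows; pandas names the line
        raise BismarkParseError(f"{path}: {exc}") from exc
    if raw.shape[1] != 6:
        raise BismarkParseError(
            f"{path}: expected 6 tab-separated columns, found {raw.shape[1]}"
        )
    num = raw.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise BismarkParseError(f"{path}: non-numeric field on line {line}")
    start = num.iloc[:, 0].to_numpy()
    end = num.iloc[:, 1].to_numpy()
    if np.any(start != end):
        line = int(np.flatnonzero(start != end)[0]) + 1
        raise BismarkParseError(f"{path}: start != end on line {line}")
    count_m = num.iloc[:, 3].to_numpy()
    count_u = num.iloc[:, 4].to_numpy()
    if np.any(count_m < 0) or np.any(count_u < 0) or \
            np.any(count_m != np.floor(count_m)) or np.any(count_u != np.floor(count_u)):
        bad_rows = (count_m < 0) | (count_u < 0) | (count_m % 1 != 0) | (count_u % 1 != 0)
        line = int(np.flatnonzero(bad_rows)[0]) + 1
        raise BismarkParseError(f"{path}: counts must be non-negative integers (line {line})")
    total = count_m + count_u
    keep = total > 0
    table = pd.DataFrame({
        "chrom": raw.iloc[:, 0].to_numpy()[keep],
        "pos": start[keep].astype(np.int64),
        "strand": ".",
        "beta": count_m[keep] / total[keep],
        "coverage": total[keep].astype(np.int64),
    })
    if sample_id is not None:
        table.attrs["sample_id"] = sample_id
    return sort_sites(table)


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a generic per-site TSV (chrom, pos, strand, beta, coverage[, sample])."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return sort_sites(table)


# ---------------------------------------------------------------------------
# assembling the matrix
# ---------------------------------------------------------------------------

def unite_samples(
    tables: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    groups: Mapping[str, str] | None = None,
    min_coverage: int = 10,
    strategy: str = "intersect",
) -> MethylationMatrix:
    """Combine per-sample site tables into one :class:`MethylationMatrix`.

    Sites whose coverage in a sample falls below `min_coverage` are treated as
    missing in that sample.  ``strategy="intersect"`` keeps only sites observed
    (post-threshold) in every sample; ``"union"`` keeps every site ever observed.
    """
    if strategy not in {"intersect", "union"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    pairs = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    if not pairs:
        raise ValueError("at least one sample table is required")
    sample_ids = [s for s, _ in pairs]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
        raise ValueError(f"duplicate sample id(s): {sorted(dupes)}")

    chrom_order = _order_chroms(
        c for _, t in pairs for c in _order_chroms(t["chrom"])
    )
    all_sites = pd.concat(
        [t[["chrom", "pos", "strand"]] for _, t in pairs], ignore_index=True
    ).drop_duplicates(subset=["chrom", "pos"], keep="first")
    all_sites = sort_sites(all_sites, chrom_order)

    key = pd.MultiIndex.from_frame(all_sites[["chrom", "pos"]])
    n = len(all_sites)
    beta = np.full((n, len(pairs)), np.nan)
    coverage = np.zeros((n, len(pairs)), dtype=np.int64)
    for j, (_, t) in enumerate(pairs):
        idx = key.get_indexer(pd.MultiIndex.from_frame(t[["chrom", "pos"]]))
        beta[idx, j] = t["beta"].to_numpy()
        coverage[idx, j] = t["coverage"].to_numpy()
    low = coverage < min_coverage
    beta[low] = np.nan
    coverage[low] = 0

    if strategy == "intersect":
        keep = ~np.isnan(beta).any(axis=1)
        if not keep.any():
            logger.warning("unite_samples: empty intersection across %d samples", len(pairs))
        all_sites = all_sites.loc[keep].reset_index(drop=True)
        beta, coverage = beta[keep], coverage[keep]

    group_map = dict(groups) if groups else {s: "all" for s in sample_ids}
    return MethylationMatrix(all_sites, sample_ids, beta, coverage, group_map)


def filter_by_coverage(
    matrix: MethylationMatrix,
    min_count: int = 10,
    max_percentile: float = 0.999,
) -> MethylationMatrix:
    """Mask per-sample outlier coverage: below `min_count` or above the
    sample's `max_percentile` coverage quantile.  The site list is unchanged;
    masked entries become missing."""
    if not 0 < max_percentile <= 1:
        raise ValueError("max_percentile must lie in (0, 1]")
    beta = matrix.beta.copy()
    coverage = matrix.coverage.copy()
    for j in range(len(matrix.samples)):
        covered = coverage[:, j] > 0
        if not covered.any():
            continue
        upper = np.quantile(coverage[covered, j], max_percentile)
        mask = covered & ((coverage[:, j] < min_count) | (coverage[:, j] > upper))
        beta[mask, j] = np.nan
        coverage[mask, j] = 0
    return MethylationMatrix(
        matrix.sites.copy(), list(matrix.samples), beta, coverage, dict(matrix.groups)
    )


# ---------------------------------------------------------------------------
# region I/O
# ---------------------------------------------------------------------------

def validate_regions(regions: pd.DataFrame) -> None:
    missing = [c for c in ("chrom", "start", "end", "id") if c not in regions.columns]
    if missing:
        raise ValueError(f"region table missing columns {missing}")
    if len(regions) and (regions["start"] > regions["end"]).any():
        raise ValueError("region with start > end")


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED (0-based half-open); internal [start, end] maps to
    (start - 1, end)."""
    validate_regions(regions)
    bed = pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"] - 1,
        "end": regions["end"],
        "name": regions["id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: str | Path, provenance: str = "fixed") -> pd.DataFrame:
    """Read a BED file into an internal 1-based inclusive region table."""
    try:
        bed = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=REGION_COLUMNS)
    out = pd.DataFrame({
        "chrom": bed.iloc[:, 0],
        "start": bed.iloc[:, 1].astype(np.int64) + 1,
        "end": bed.iloc[:, 2].astype(np.int64),
    })
    if bed.shape[1] > 3:
        out["id"] = bed.iloc[:, 3].astype(str)
    else:
        out["id"] = [f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])]
    out["provenance"] = provenance
    out["source"] = out["id"]
    return out


def write_regions_tsv(regions: pd.DataFrame, path: str | Path) -> None:
    """Write the internal 1-based inclusive region table (with provenance)."""
    validate_regions(regions)
    cols = [c for c in REGION_COLUMNS if c in regions.columns]
    regions[cols].to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str | Path) -> pd.DataFrame:
    regions = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    validate_regions(regions)
    return regions


def write_region_stats_tsv(stats: pd.DataFrame, path: str | Path) -> None:
    """Write a region statistics table; NaN is encoded as ``NA``.

    ``read_region_stats_tsv(write_region_stats_tsv(x)) == x`` (float columns
    round-trip at full precision)."""
    stats.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_region_stats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str},
        na_values=["NA"], keep_default_na=False,
    )
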