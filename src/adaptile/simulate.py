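"""Synthetic RRBS-like methylation data with known ground truth.

The generator emulates the CpG landscape that targeted bisulfite protocols
produce: dense island-like CpG clusters (geometric spacing, mean ~10 bp)
scattered over a sparse background (mean ~1000 bp).  Island CpGs are
unmethylated on average (beta ~0.05), background CpGs methylated (~0.85).
Three region-level regimes carry the ground-truth labels used in recovery
tests:

* ``clean`` islands — all CpGs share a low mean; within-region SD is small;
* ``heterogeneous`` islands — each CpG gets its own mean drawn i.i.d. from
  U(0.1, 0.9), mimicking regulatory heterogeneity;
* ``snp_outlier`` sites — background CpGs forced to beta 0 in every sample,
  the signature of a polymorphism that destroys the CpG: one fully
  unmethylated site inside an otherwise methylated neighbourhood.

Observed betas are binomially resampled at a negative-binomially distributed
read coverage, so shallow sites are noisier, exactly as in real coverage files.
All randomness flows from a single seed through spawned generators, so the
landscape is reproducible independently of the beta draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from adaptile.io import MethylationMatrix, sort_sites

DEFAULT_CHROM_LENGTHS = {"chr1": 2_000_000}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic RRBS generator (defaults are the study
    conditions used throughout the test-suite recovery checks)."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_islands: int = 40                         #: islands per chromosome
    island_length_range: tuple[int, int] = (300, 1500)   #: bp, uniform
    island_spacing_mean: float = 10.0           #: bp, geometric within islands
    background_spacing_mean: float = 1000.0     #: bp, geometric background
    n_samples: int = 4
    group_labels: tuple[str, ...] = ("case", "control")  #: samples split evenly
    island_beta_mean: float = 0.05
    background_beta_mean: float = 0.85
    beta_noise_sd: float = 0.02                 #: per-sample truncated-normal noise
    snp_outlier_rate: float = 0.02              #: P(background CpG forced to 0)
    heterogeneous_region_rate: float = 0.15     #: P(island is heterogeneous)
    heterogeneous_beta_range: tuple[float, float] = (0.1, 0.9)
    coverage_mean: float = 30.0                 #: negative binomial mean
    coverage_dispersion: float = 5.0            #: negative binomial size r

    def __post_init__(self) -> None:
        for p in (self.snp_outlier_rate, self.heterogeneous_region_rate,
                  self.island_beta_mean, self.background_beta_mean):
            if not 0 <= p <= 1:
                raise ValueError("probabilities and beta means must lie in [0, 1]")
        if min(self.island_spacing_mean, self.background_spacing_mean,
               self.coverage_mean, self.coverage_dispersion) <= 0:
            raise ValueError("distribution parameters must be positive")
        if self.n_samples < 1 or self.n_islands < 0:
            raise ValueError("n_samples >= 1 and n_islands >= 0 required")

    @property
    def samples(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]

    @property
    def groups(self) -> dict[str, str]:
        g = self.group_labels
        return {s: g[i * len(g) // self.n_samples] for i, s in enumerate(self.samples)}


@dataclass
class SimulationTruth:
    """Ground truth returned by the generator for recovery tests."""

    islands: pd.DataFrame      #: chrom, start, end, island_id, scenario (clean|heterogeneous)
    outliers: pd.DataFrame     #: chrom, pos of SNP-like forced-zero sites
    true_beta: np.ndarray      #: per (site, sample) true methylation proportion


def _geometric_positions(rng: np.random.Generator, start: int, stop: int, mean: float) -> np.ndarray:
    """Positions from `start` with geometric gaps (mean `mean`), up to `stop`."""
    n_guess = max(16, int(2.5 * (stop - start) / mean) + 8)
    gaps = rng.geometric(1.0 / mean, size=n_guess)
    pos = start + np.concatenate(([0], np.cumsum(gaps)))
    while pos[-1] <= stop:
        gaps = rng.geometric(1.0 / mean, size=n_guess)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(gaps)])
    return pos[pos <= stop]


def simulate_cpg_landscape(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay down island and background CpG positions.

    Returns ``(sites, islands)``: a site table (chrom, pos, strand) and the
    ground-truth island intervals (span of each island's first to last CpG).
    Each island contains at least 2 CpGs by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    site_rows = []
    island_rows = []
    for chrom, length in config.chrom_lengths.items():
        max_len = config.island_length_range[1]
        slot = length // max(config.n_islands, 1)
        if config.n_islands and slot < 2 * max_len:
            raise ValueError(
                f"{chrom} ({length} bp) too short for {config.n_islands} islands "
                f"of up to {max_len} bp"
            )
        island_intervals = []
        for k in range(config.n_islands):
            ilen = int(rng.integers(*config.island_length_range, endpoint=True))
            lo = k * slot + max_len // 2
            hi = (k + 1) * slot - max_len - max_len // 2
            istart = int(rng.integers(lo, max(lo + 1, hi)))
            pos = _geometric_positions(rng, istart, istart + ilen - 1,
                                       config.island_spacing_mean)
            if len(pos) < 2:   # vanishingly rare at the default spacing
                pos = np.array([istart, istart + ilen - 1])
            island_intervals.append((int(pos[0]), int(pos[-1])))
            site_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "island": k}))
            island_rows.append({
                "chrom": chrom, "start": int(pos[0]), "end": int(pos[-1]),
                "island_id": f"{chrom}_island{k}",
            })
        background = _geometric_positions(rng, 1, length, config.background_spacing_mean)
        for istart, iend in island_intervals:
            background = background[(background < istart) | (background > iend)]
        site_rows.append(pd.DataFrame({"chrom": chrom, "pos": background, "island": -1}))

    sites = pd.concat(site_rows, ignore_index=True) if site_rows else \
        pd.DataFrame(columns=["chrom", "pos", "island"])
    sites["pos"] = sites["pos"].astype(np.int64)
    sites = sites.drop_duplicates(subset=["chrom", "pos"])
    sites["strand"] = "."
    sites = sort_sites(sites[["chrom", "pos", "strand", "island"]],
                       list(config.chrom_lengths))
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end", "island_id"])
    return sites, islands


def simulate_betas(
    sites: pd.DataFrame,
    islands: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[MethylationMatrix, SimulationTruth]:
    """Draw per-sample betas and coverages over a simulated landscape.

    True per-site means follow the island/background architecture; per-sample
    betas add truncated-normal noise; observed betas are
    ``Binomial(coverage, beta) / coverage`` with negative-binomial coverage
    (beta missing where coverage is 0).
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_arch = np.random.default_rng(ss[1])
    rng_obs = np.random.default_rng(ss[2])
    n = len(sites)
    n_samp = config.n_samples
    island_of = sites["island"].to_numpy() if "island" in sites else np.full(n, -1)

    scenario = np.where(
        rng_arch.random(len(islands)) < config.heterogeneous_region_rate,
        "heterogeneous", "clean",
    )
    islands = islands.assign(scenario=scenario)

    true_mean = np.full(n, config.background_beta_mean)
    for k, scen in enumerate(scenario):
        in_island = island_of == k
        if scen == "clean":
            true_mean[in_island] = config.island_beta_mean
        else:
            lo, hi = config.heterogeneous_beta_range
            true_mean[in_island] = rng_arch.uniform(lo, hi, in_island.sum())

    background = island_of == -1
    forced_zero = background & (rng_arch.random(n) < config.snp_outlier_rate)
    true_mean[forced_zero] = 0.0

    true_beta = np.clip(
        true_mean[:, None] + rng_obs.normal(0.0, config.beta_noise_sd, (n, n_samp)),
        0.0, 1.0,
    )
    true_beta[forced_zero] = 0.0   # the destroyed CpG reads unmethylated in all samples

    r = config.coverage_dispersion
    p = r / (r + config.coverage_mean)
    coverage = rng_obs.negative_binomial(r, p, (n, n_samp))
    meth = rng_obs.binomial(coverage, true_beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(coverage > 0, meth / np.maximum(coverage, 1), np.nan)

    matrix = MethylationMatrix(
        sites[["chrom", "pos", "strand"]].copy(),
        config.samples, beta, coverage, config.groups,
    )
    outliers = sites.loc[forced_zero, ["chrom", "pos"]].reset_index(drop=True)
    truth = SimulationTruth(islands=islands, outliers=outliers, true_beta=true_beta)
    return matrix, truth


def simulate_dataset(config: SimulationConfig) -> tuple[MethylationMatrix, SimulationTruth]:
    """Landscape + betas in one call (single-seed reproducible)."""
    sites, islands = simulate_cpg_landscape(config)
    return simulate_betas(sites, islands, config)


def write_simulated_bismark(matrix: MethylationMatrix, out_dir: str | Path) -> list[Path]:
    """Write one Bismark coverage file per sample (zero-coverage sites omitted).

    ``read_bismark_coverage`` round-trips these files exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sample in enumerate(matrix.samples):
        cov = matrix.coverage[:, j]
        covered = cov > 0
        meth = np.rint(matrix.beta[covered, j] * cov[covered]).astype(np.int64)
        df = pd.DataFrame({
            "chrom": matrix.sites["chrom"].to_numpy()[covered],
            "start": matrix.sites["pos"].to_numpy()[covered],
            "end": matrix.sites["pos"].to_numpy()[covered],
            "pct": 100.0 * meth / cov[covered],
            "meth": meth,
            "unmeth": cov[covered] - meth,
        })
        path = out_dir / f"{sample}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def label_regions(
    regions: pd.DataFrame,
    truth: SimulationTruth,
) -> pd.Series:
    """Ground-truth label per region id.

    Priority: a region containing a forced-zero outlier site is
    ``snp_outlier``; else a region overlapping a heterogeneous island is
    ``heterogeneous``; else overlapping a clean island, ``clean``; else
    ``background``.
    """
    labels = pd.Series("background", index=regions["id"].to_list(), dtype=object)
    out_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in truth.outliers.groupby("chrom")}
    isl = truth.islands
    for rec in regions.itertuples(index=False):
        pos = out_by_chrom.get(rec.chrom)
        if pos is not None and np.searchsorted(pos, rec.end, "right") > np.searchsorted(pos, rec.start, "left"):
            labels[rec.id] = "snp_outlier"
            continue
        hits = isl[(isl["chrom"] == rec.chrom) & (isl["start"] <= rec.end) & (isl["end"] >= rec.start)]
        if len(hits):
            labels[rec.id] = "heterogeneous" if (hits["scenario"] == "heterogeneous").any() else "clean"
    return labels


def config_to_dict(config: SimulationConfig) -> dict:
    """YAML-serialisable form of a config (tuples become lists)."""
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
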