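"""Intra-region methylation variability, CpG density, and the InfoScore.

Summarising a region by its mean beta value hides whether the CpGs inside it
actually agree.  A single aberrant site (e.g. a SNP destroying the CpG, read as
fully unmethylated) or genuinely heterogeneous methylation both inflate the
within-region standard deviation, while a uniformly (un)methylated CpG island
keeps it near zero.  The InfoScore combines this with CpG density:

    info_score = density / sd    (density = n_cpg / region length, CpGs per bp)

so that dense, internally consistent regions rank highest.  High-variability
regions are flagged, never removed: the flag marks candidates for closer
inspection (SNP, technical noise, or regulatory heterogeneity), not exclusion.
"""

from __future__ import annotations

import math
import warnings
from contextlib import contextmanager

import numpy as np
import pandas as pd

from adaptile.io import MethylationMatrix
from adaptile.tiling import RegionCpGMap

SD_AGGREGATIONS = ("mean", "median", "pooled")


@contextmanager
def _allow_empty_slices():
    """NaN means/SDs over all-missing slices are legitimate 'undefined' results."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        warnings.filterwarnings("ignore", message="All-NaN slice")
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message="invalid value encountered")
        with np.errstate(invalid="ignore", divide="ignore"):
            yield


def compute_region_means(
    matrix: MethylationMatrix,
    cpg_map: RegionCpGMap,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-region, per-sample mean beta over the region's CpGs.

    Missing betas are excluded.  With ``weighted=True`` the mean is coverage
    weighted (sum cov*beta / sum cov), down-weighting shallow sites.
    """
    rows = {}
    for rid, idx in cpg_map.indices.items():
        beta = matrix.beta[idx]
        if weighted:
            cov = matrix.coverage[idx].astype(float)
            cov[np.isnan(beta)] = 0.0
            with _allow_empty_slices():
                rows[rid] = np.nansum(beta * cov, axis=0) / cov.sum(axis=0)
        else:
            with _allow_empty_slices():
                rows[rid] = np.nanmean(beta, axis=0) if len(idx) else np.full(len(matrix.samples), np.nan)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.samples)


def compute_beta_sd_regions(
    matrix: MethylationMatrix,
    cpg_map: RegionCpGMap,
    agg: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-region SD of beta values, per sample, aggregated per group.

    The sample SD uses the n-1 denominator over that sample's non-missing
    betas in the region; fewer than two informative CpGs leaves it undefined
    (NaN, never coerced to zero).  Group aggregation over member samples:

    * ``mean`` (default) / ``median`` of the per-sample SDs (samples with
      undefined SD are skipped; all-undefined stays undefined);
    * ``pooled``: sqrt of the (n_s - 1)-weighted mean of per-sample variances.

    Returns ``(sd_by_sample, sd_by_group)``, regions as rows.
    """
    if agg not in SD_AGGREGATIONS:
        raise ValueError(f"agg must be one of {SD_AGGREGATIONS}")
    for g in set(matrix.groups.values()):
        if g not in matrix.group_labels:
            raise ValueError(f"unknown group label {g!r}")

    region_ids = list(cpg_map.indices)
    n_samp = len(matrix.samples)
    sd = np.full((len(region_ids), n_samp), np.nan)
    n_inf = np.zeros((len(region_ids), n_samp), dtype=np.int64)
    for r, rid in enumerate(region_ids):
        beta = matrix.beta[cpg_map.indices[rid]]
        n_inf[r] = np.sum(~np.isnan(beta), axis=0)
        enough = n_inf[r] >= 2
        if enough.any():
            with _allow_empty_slices():
                col_sd = np.nanstd(beta, axis=0, ddof=1)
            sd[r, enough] = col_sd[enough]
    sd_by_sample = pd.DataFrame(sd, index=region_ids, columns=matrix.samples)

    group_cols = {}
    for g in matrix.group_labels:
        members = [matrix.samples.index(s) for s in matrix.group_samples(g)]
        block = sd[:, members]
        with _allow_empty_slices():
            if agg == "mean":
                group_cols[g] = np.nanmean(block, axis=1)
            elif agg == "median":
                group_cols[g] = np.nanmedian(block, axis=1)
            else:  # pooled within-sample variance
                w = np.maximum(n_inf[:, members] - 1, 0).astype(float)
                w[np.isnan(block)] = 0.0
                var = np.square(block)
                group_cols[g] = np.sqrt(np.nansum(var * w, axis=1) / w.sum(axis=1))
    sd_by_group = pd.DataFrame(group_cols, index=region_ids)
    return sd_by_sample, sd_by_group


def compute_infoscore(
    density: pd.Series,
    sd_by_group: pd.DataFrame,
    sd_floor: float = 0.0,
) -> pd.DataFrame:
    """InfoScore = CpG density / within-region SD, per region and group.

    ``sd_floor`` clamps the denominator from below; with the default floor of
    0, a zero SD yields +infinity (such regions rank highest).  Undefined SD
    propagates to an undefined score.
    """
    if sd_floor < 0:
        raise ValueError("sd_floor must be >= 0")
    dens = density.reindex(sd_by_group.index).to_numpy()[:, None]
    denom = np.maximum(sd_by_group.to_numpy(), sd_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = dens / denom
    return pd.DataFrame(score, index=sd_by_group.index, columns=sd_by_group.columns)


def flag_high_variability(
    sd_by_group: pd.DataFrame,
    threshold: float | None = None,
    quantile: float = 0.9,
) -> pd.DataFrame:
    """Boolean high-variability flag per region and group.

    With an absolute ``threshold``, flag ``sd > threshold``.  Otherwise the
    ``quantile`` mode flags, within each group, the ``ceil(n * (1 - quantile))``
    regions of highest SD among the n regions with a defined SD (ties broken by
    region order: earlier regions win).  Regions with undefined SD are never
    flagged.  Flagged regions are retained, not removed.
    """
    if threshold is not None:
        return sd_by_group.gt(threshold).fillna(False)
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    flags = pd.DataFrame(False, index=sd_by_group.index, columns=sd_by_group.columns)
    for g in sd_by_group.columns:
        sd = sd_by_group[g].to_numpy(dtype=float)
        defined = np.flatnonzero(~np.isnan(sd))
        if defined.size == 0:
            continue
        k = math.ceil(defined.size * (1 - quantile))
        # stable sort on (-sd, region order): earliest region wins on ties
        order = defined[np.argsort(-sd[defined], kind="stable")]
        flags.iloc[order[:k], flags.columns.get_loc(g)] = True
    return flags


def region_stats(
    matrix: MethylationMatrix,
    regions: pd.DataFrame,
    cpg_map: RegionCpGMap,
    *,
    weighted_mean: bool = False,
    sd_agg: str = "mean",
    sd_floor: float = 0.0,
    flag_threshold: float | None = None,
    flag_quantile: float = 0.9,
) -> pd.DataFrame:
    """Assemble the per-region x per-group statistics table.

    One row per (region, group): CpG count, length, density, group mean beta
    (mean of member-sample means), group SD, InfoScore and the high-variability
    flag.  This is the table :func:`adaptile.io.write_region_stats_tsv` writes.
    """
    length = (regions["end"] - regions["start"] + 1).to_numpy()
    n_cpg = np.array([cpg_map.n_cpg(rid) for rid in regions["id"]])
    density = pd.Series(n_cpg / length, index=regions["id"])

    means = compute_region_means(matrix, cpg_map, weighted=weighted_mean)
    sd_by_sample, sd_by_group = compute_beta_sd_regions(matrix, cpg_map, agg=sd_agg)
    scores = compute_infoscore(density, sd_by_group, sd_floor=sd_floor)
    flags = flag_high_variability(sd_by_group, threshold=flag_threshold, quantile=flag_quantile)

    rows = []
    for i, rid in enumerate(regions["id"]):
        for g in sd_by_group.columns:
            members = matrix.group_samples(g)
            with _allow_empty_slices():
                gmean = np.nanmean(means.loc[rid, members].to_numpy(dtype=float))
            rows.append({
                "region_id": rid,
                "chrom": regions["chrom"].iat[i],
                "start": regions["start"].iat[i],
                "end": regions["end"].iat[i],
                "provenance": regions["provenance"].iat[i] if "provenance" in regions else "fixed",
                "group": g,
                "n_cpg": int(n_cpg[i]),
                "length": int(length[i]),
                "density": density.iat[i],
                "mean_beta": gmean,
                "sd_beta": sd_by_group.loc[rid, g],
                "info_score": scores.loc[rid, g],
                "high_variability": bool(flags.loc[rid, g]),
            })
    return pd.DataFrame(rows)
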