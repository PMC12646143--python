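"""Map regions to genomic features and score overlaps.

Two complementary overlap metrics are attached to every region/feature pair:
the percentage of the region's base pairs covered by the feature, and the
number of the region's CpGs that fall inside the intersection.  A region can
overlap a feature extensively yet contain few informative CpGs there (or vice
versa); filtering on both at once keeps associations that are spatially
extensive *and* CpG-rich.

Annotations come from local GFF3/GTF or BED files (GFF/GTF are 1-based
inclusive; BED is converted from 0-based half-open).  Promoter features are
derived from gene TSSs with a strand-aware upstream/downstream window.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator
from intervaltree import IntervalTree

from adaptile.io import MethylationMatrix
from adaptile.tiling import RegionCpGMap

logger = logging.getLogger("adaptile")

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "feature_type", "feature_id", "name", "biotype"]

_BIOTYPE_KEYS = ("gene_biotype", "biotype", "gene_type", "transcript_biotype")


def _first(attrs, *keys) -> str | None:
    for k in keys:
        if k in attrs and len(attrs[k]):
            return attrs[k][0]
    return None


def load_features(
    path: str | Path,
    chromosomes: Iterable[str] | None = None,
    biotypes: Iterable[str] | None = None,
    feature_types: Iterable[str] | None = None,
    bed_feature_type: str = "interval",
) -> pd.DataFrame:
    """Load annotation features from GFF3/GTF or BED with optional filters.

    Format is inferred from the extension (``.bed`` vs ``.gff/.gff3/.gtf``,
    ``.gz`` allowed).  Filters are conjunctive; a biotype filter excludes
    features that carry no biotype attribute (the count is logged).  Output is
    sorted by (chrom, start).
    """
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes]
    stem_suffix = suffixes[-2] if suffixes and suffixes[-1] == ".gz" and len(suffixes) > 1 else (
        suffixes[-1] if suffixes else ""
    )
    if stem_suffix == ".bed":
        feats = _load_bed(path, bed_feature_type)
    elif stem_suffix in {".gff", ".gff3", ".gtf"}:
        feats = _load_gff(path)
    else:
        raise ValueError(f"unrecognized annotation format: {path.name}")

    if chromosomes is not None:
        feats = feats[feats["chrom"].isin(set(chromosomes))]
    if feature_types is not None:
        feats = feats[feats["feature_type"].isin(set(feature_types))]
    if biotypes is not None:
        no_biotype = feats["biotype"].isna()
        if no_biotype.any():
            logger.info("biotype filter: %d features without a biotype attribute excluded",
                        int(no_biotype.sum()))
        feats = feats[feats["biotype"].isin(set(biotypes))]
    feats = feats.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return feats


def _load_bed(path: Path, feature_type: str) -> pd.DataFrame:
    try:
        bed = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    out = pd.DataFrame({
        "chrom": bed.iloc[:, 0],
        "start": bed.iloc[:, 1].astype(np.int64) + 1,
        "end": bed.iloc[:, 2].astype(np.int64),
        "strand": bed.iloc[:, 5] if bed.shape[1] > 5 else ".",
        "feature_type": feature_type,
    })
    if bed.shape[1] > 3:
        out["feature_id"] = bed.iloc[:, 3].astype(str)
    else:
        out["feature_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])]
    out["name"] = out["feature_id"]
    out["biotype"] = pd.NA
    return out


def _load_gff(path: Path) -> pd.DataFrame:
    rows = []
    for f in DataIterator(str(path)):
        rows.append({
            "chrom": f.seqid,
            "start": int(f.start),
            "end": int(f.end),
            "strand": f.strand or ".",
            "feature_type": f.featuretype,
            "feature_id": _first(f.attributes, "ID", "gene_id", "transcript_id")
            or f"{f.featuretype}:{f.seqid}:{f.start}-{f.end}",
            "name": _first(f.attributes, "Name", "gene_name", "gene_id"),
            "biotype": _first(f.attributes, *_BIOTYPE_KEYS),
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def promoters_from_tss(
    genes: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 200,
) -> pd.DataFrame:
    """Strand-aware promoter windows around gene TSSs.

    On the + strand the TSS is the gene start and the promoter is
    ``[TSS - upstream, TSS + downstream]``; on the - strand the TSS is the gene
    end and the window mirrors to ``[TSS - downstream, TSS + upstream]``.
    Coordinates are clipped at 1.  Unstranded genes are skipped with a warning.
    """
    rows = []
    skipped = 0
    for rec in genes.itertuples(index=False):
        if rec.strand == "+":
            tss = rec.start
            start, end = tss - upstream, tss + downstream
        elif rec.strand == "-":
            tss = rec.end
            start, end = tss - downstream, tss + upstream
        else:
            skipped += 1
            continue
        rows.append({
            "chrom": rec.chrom,
            "start": max(1, start),
            "end": end,
            "strand": rec.strand,
            "feature_type": "promoter",
            "feature_id": f"promoter:{rec.feature_id}",
            "name": getattr(rec, "name", rec.feature_id),
            "biotype": getattr(rec, "biotype", pd.NA),
        })
    if skipped:
        logger.warning("promoters_from_tss: %d unstranded gene(s) skipped", skipped)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def overlap_regions_features(
    regions: pd.DataFrame,
    cpg_map: RegionCpGMap,
    matrix: MethylationMatrix,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """One record per overlapping (region, feature) pair.

    ``overlap_bp`` is the length of the coordinate intersection (>= 1 by
    construction; disjoint pairs emit nothing), ``pct_overlap`` normalises it
    by the REGION length (the feature-normalised percentage is emitted as the
    secondary ``pct_overlap_feature`` column), and ``n_cpg_in_overlap`` counts
    the region's mapped CpGs inside the intersection.  ``distance_to_tss`` is
    the signed bp offset of the region midpoint from the feature's TSS
    (positive downstream), defined only for stranded features.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, rec in enumerate(features.itertuples(index=False)):
        # half-open interval [start, end + 1) represents the inclusive feature
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end + 1, idx)

    records = []
    for rec in regions.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        rlen = rec.end - rec.start + 1
        pos = cpg_map.positions(rec.id, matrix) if rec.id in cpg_map else np.empty(0, dtype=np.int64)
        mid = (rec.start + rec.end) / 2
        for hit in sorted(tree.overlap(rec.start, rec.end + 1), key=lambda h: (h.begin, h.data)):
            feat = features.iloc[hit.data]
            o_start = max(rec.start, feat["start"])
            o_end = min(rec.end, feat["end"])
            overlap_bp = o_end - o_start + 1
            n_in = int(np.searchsorted(pos, o_end, side="right")
                       - np.searchsorted(pos, o_start, side="left"))
            if feat["strand"] == "+":
                dist = mid - feat["start"]
            elif feat["strand"] == "-":
                dist = feat["end"] - mid
            else:
                dist = np.nan
            records.append({
                "region_id": rec.id,
                "feature_id": feat["feature_id"],
                "feature_type": feat["feature_type"],
                "overlap_bp": int(overlap_bp),
                "pct_overlap": 100.0 * overlap_bp / rlen,
                "pct_overlap_feature": 100.0 * overlap_bp / (feat["end"] - feat["start"] + 1),
                "n_cpg_in_overlap": n_in,
                "distance_to_tss": dist,
            })
    return pd.DataFrame(records, columns=[
        "region_id", "feature_id", "feature_type", "overlap_bp", "pct_overlap",
        "pct_overlap_feature", "n_cpg_in_overlap", "distance_to_tss",
    ])


def filter_overlaps(
    records: pd.DataFrame,
    min_pct: float = 0.0,
    min_cpg: int = 0,
) -> pd.DataFrame:
    """Keep records with ``pct_overlap >= min_pct`` and
    ``n_cpg_in_overlap >= min_cpg`` (both must hold)."""
    if not 0 <= min_pct <= 100:
        raise ValueError("min_pct must lie in [0, 100]")
    keep = (records["pct_overlap"] >= min_pct) & (records["n_cpg_in_overlap"] >= min_cpg)
    return records.loc[keep].reset_index(drop=True)
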