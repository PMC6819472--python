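"""Allelic quantitation: counting, informativeness filters, normalisation.

Reads are attributed to regions by the midpoint-overlap rule (a read
counts once per region containing its midpoint), which keeps counts
additive across merged peaks and tiled windows.  The informativeness
filter retains a region when maternal + paternal reads reach the assay
threshold (20 for ChIP-type assays, 5 for RNA) in at least one
allelically mapped replicate of any sample.  Library-size correction is
median-of-ratios size-factor normalisation estimated on autosomal
regions only; display tracks use RPKM over running windows and an
optional enrichment normalisation anchored to the 40th and 99th
percentiles of the non-zero values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Gene, GenomicInterval, Peak, ReadRecord, is_autosome

logger = logging.getLogger("imprintseq")

#: minimum mat+pat reads in >= 1 replicate for a region to be informative
INFORMATIVE_THRESHOLDS = {"chip": 20, "rna": 5}


# ---------------------------------------------------------------------------
# Peak-set consensus
# ---------------------------------------------------------------------------

def merge_peak_sets(peaks_cross1: list[Peak], peaks_cross2: list[Peak]) -> list[Peak]:
    """Combine and de-duplicate peak sets from the two reciprocal crosses.

    Peaks overlapping by >= 1 bp are merged into their union interval under
    a new stable id; non-overlapping peaks pass through.  Both sets must
    come from the same tissue and mark.
    """
    tissues = {p.tissue for p in peaks_cross1} | {p.tissue for p in peaks_cross2}
    marks = {p.mark for p in peaks_cross1} | {p.mark for p in peaks_cross2}
    if len(tissues) > 1 or len(marks) > 1:
        raise ValueError(f"mixed tissues/marks in peak merge: {tissues}, {marks}")
    combined = sorted(peaks_cross1 + peaks_cross2,
                      key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    merged: list[Peak] = []
    out_idx = 0
    for peak in combined:
        if merged and merged[-1].interval.overlaps(peak.interval):
            prev = merged[-1]
            union = GenomicInterval(
                prev.interval.chrom,
                min(prev.interval.start, peak.interval.start),
                max(prev.interval.end, peak.interval.end),
            )
            merged[-1] = Peak(prev.id, union, prev.mark, prev.tissue)
        else:
            merged.append(Peak(f"consensus_{out_idx:05d}", peak.interval,
                               peak.mark, peak.tissue))
            out_idx += 1
    return merged


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountRegion:
    """A counting target: a region with an id and a kind."""

    region_id: str
    interval: GenomicInterval
    kind: str = "peak"  # peak / gene / window / ltr
    exons: tuple = ()  # populated for kind == "gene" (RNA counting)


def regions_from_peaks(peaks: list[Peak]) -> list[CountRegion]:
    return [CountRegion(p.id, p.interval, "peak") for p in peaks]


def regions_from_genes(genes: list[Gene]) -> list[CountRegion]:
    return [CountRegion(g.id, g.interval, "gene", g.exons) for g in genes]


def _read_hits_region(read: ReadRecord, region: CountRegion) -> bool:
    mid = read.midpoint()
    if not region.interval.contains(read.chrom, mid):
        return False
    if region.kind == "gene" and region.exons:
        # RNA counting is exon-restricted: intronic midpoints do not count
        return any(ex.contains(read.chrom, mid) for ex in region.exons)
    if region.kind == "ltr" and region.interval.strand in "+-":
        return read.strand == region.interval.strand
    return True


def count_over_regions(partition_by_allele: dict, regions: list[CountRegion],
                       sample_id: str = "sample", replicate: int = 1) -> pd.DataFrame:
    """Allelic counts over regions from maternal/paternal/unassigned reads.

    ``partition_by_allele`` maps "maternal"/"paternal"/"unassigned" to read
    lists.  A read counts once in every region that contains its midpoint
    (windows at step < width may legitimately count a read several times);
    counting is strand-aware for kind == "ltr".
    """
    rows = []
    by_chrom: dict[str, list] = {}
    for region in regions:
        by_chrom.setdefault(region.interval.chrom, []).append(region)
    for regs in by_chrom.values():
        regs.sort(key=lambda r: r.interval.start)
    tallies = {r.region_id: {"mat": 0, "pat": 0, "unassigned": 0} for r in regions}
    key_map = {"maternal": "mat", "paternal": "pat", "unassigned": "unassigned"}
    for allele, reads in partition_by_allele.items():
        col = key_map[allele]
        for read in reads:
            for region in by_chrom.get(read.chrom, ()):
                if region.interval.start > read.end:
                    break
                if _read_hits_region(read, region):
                    tallies[region.region_id][col] += 1
    for region in regions:
        t = tallies[region.region_id]
        rows.append({"region_id": region.region_id, "sample_id": sample_id,
                     "replicate": replicate, "mat": t["mat"], "pat": t["pat"],
                     "unassigned": t["unassigned"], "region_kind": region.kind})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Informativeness filter
# ---------------------------------------------------------------------------

def filter_informative(counts: pd.DataFrame, assay: str,
                       threshold: int | None = None) -> list[str]:
    """Region ids with mat+pat >= threshold in at least one replicate.

    The threshold counts allelically mapped (SNP-spanning) reads only —
    unassigned reads do not contribute.
    """
    if threshold is None:
        if assay not in INFORMATIVE_THRESHOLDS:
            raise ValueError(f"unknown assay {assay!r}; expected chip or rna")
        threshold = INFORMATIVE_THRESHOLDS[assay]
    allelic = counts["mat"] + counts["pat"]
    retained = counts.loc[allelic >= threshold, "region_id"].unique()
    keep = set(retained)
    # preserve input region order
    seen: list[str] = []
    for rid in counts["region_id"]:
        if rid in keep:
            seen.append(rid)
            keep.remove(rid)
    return seen


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def size_factor_normalize(matrix: pd.DataFrame,
                          chrom_by_region: dict | None = None
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors (geometric-mean pseudo-reference).

    ``matrix`` is regions x samples.  Factors are estimated on autosomal
    regions with positive counts in every sample; sex and mitochondrial
    regions are scaled but never used for estimation.  Returns the scaled
    matrix (counts / factor) and the factors.
    """
    if matrix.shape[1] < 2:
        raise ValueError("size-factor normalisation needs >= 2 samples")
    use = matrix
    if chrom_by_region is not None:
        autosomal = [r for r in matrix.index if is_autosome(chrom_by_region.get(r, r))]
        use = matrix.loc[autosomal]
    positive = use[(use > 0).all(axis=1)]
    if positive.empty:
        logger.warning("no region positive in all samples; "
                       "falling back to total-count ratios")
        totals = use.sum(axis=0).astype(float)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        log_ref = np.log(positive).mean(axis=1)
        log_ratios = np.log(positive).sub(log_ref, axis=0)
        factors = np.exp(log_ratios.median(axis=0))
    factors = pd.Series(factors, index=matrix.columns, name="size_factor")
    return matrix.div(factors, axis=1), factors


def running_windows(reads: list[ReadRecord], chromosomes: dict,
                    width: int = 1000, step: int = 100,
                    library_size: int | None = None
                    ) -> tuple[list[GenomicInterval], np.ndarray]:
    """RPKM track over running windows (width 1 kb, step 100 bp by default).

    A read is attributed to every window containing its midpoint.
    RPKM = count / (library_size / 1e6) / (width / 1000).
    """
    if not (width >= step > 0):
        raise ValueError("require width >= step > 0")
    if library_size is None:
        library_size = len(reads)
    if library_size == 0:
        raise ValueError("empty library")
    windows: list[GenomicInterval] = []
    counts: list[np.ndarray] = []
    offsets = {}
    for chrom, length in chromosomes.items():
        n_win = (length - width) // step + 1 if length >= width else 0
        offsets[chrom] = (len(windows), n_win)
        for k in range(n_win):
            windows.append(GenomicInterval(chrom, k * step, k * step + width))
        counts.append(np.zeros(n_win))
    count_arr = {c: counts[i] for i, c in enumerate(chromosomes)}
    for read in reads:
        arr = count_arr.get(read.chrom)
        if arr is None or arr.size == 0:
            continue
        mid = read.midpoint()
        # windows with start in (mid - width, mid], i.e. containing mid
        k_hi = min(mid // step, arr.size - 1)
        k_lo = max(0, (mid - width) // step + 1)
        if k_lo <= k_hi:
            arr[k_lo:k_hi + 1] += 1
    values = np.concatenate([count_arr[c] for c in chromosomes]) if windows else np.array([])
    rpkm = values / (library_size / 1e6) / (width / 1000)
    return windows, rpkm


def average_replicate_tracks(tracks: list[np.ndarray]) -> np.ndarray:
    """Mean display track across biological replicates."""
    if not tracks:
        raise ValueError("no tracks to average")
    return np.mean(np.stack(tracks), axis=0)


def enrichment_normalize(values: np.ndarray, low_pct: float = 40.0,
                         high_pct: float = 99.0) -> np.ndarray:
    """Percentile-anchored affine display scaling.

    An additive translation anchors the low percentile (non-zero values
    only, representing unenriched baseline) at 0, then a multiplicative
    expansion anchors the high percentile at 1.  No clipping: relative
    enrichment and rank order are preserved.
    """
    values = np.asarray(values, dtype=float)
    nonzero = values[values != 0]
    if np.unique(nonzero).size < 2:
        raise ValueError("degenerate track: need >= 2 distinct non-zero values")
    p_low = np.percentile(nonzero, low_pct)
    p_high = np.percentile(nonzero, high_pct)
    if p_high == p_low:
        raise ValueError("degenerate track: anchor percentiles coincide")
    return (values - p_low) / (p_high - p_low)


def pooled_counts_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot long allelic counts to a region x sample total-count matrix."""
    totals = counts.assign(total=counts["mat"] + counts["pat"])
    return totals.pivot_table(index="region_id", columns="sample_id",
                              values="total", aggfunc="sum", fill_value=0)
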