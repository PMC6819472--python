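"""Imprint classification from reciprocal-cross and matDKO contrasts.

The reciprocal-cross design separates strain effects from parent-of-
origin effects: a region whose allelic bias tracks the same strain in
both cross orientations is strain-specific, whereas a bias that stays on
the same parental allele in both crosses is imprinted.  The consensus
set requires significance in both crosses; significance in exactly one
cross is recorded but excluded from consensus.

The matDKO contrast then splits imprints by mechanism: a canonical
maternal imprint depends on the maternally inherited germline DMR and
therefore loses its bias in matDKO offspring, while non-canonical
imprints (and canonical paternal imprints, recognised by their paternal
gDMR annotation) retain it.  "Lost bias" is operationalised as
non-significance AND a matDKO allelic ratio inside a balance band
(default [0.35, 0.65]) to guard against low power masquerading as loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .biastest import BiasResult
from .core_io import Gene, GenomicInterval, Peak

logger = logging.getLogger("imprintseq")

# consensus classes
BIALLELIC = "biallelic"
SINGLE_CROSS_ONLY = "single_cross_only"
STRAIN_B6 = "strain_B6"
STRAIN_CAST = "strain_CAST"
IMPRINTED_MATERNAL = "imprinted_maternal"
IMPRINTED_PATERNAL = "imprinted_paternal"
UNRESOLVED = "unresolved"

IMPRINTED_CLASSES = (IMPRINTED_MATERNAL, IMPRINTED_PATERNAL)

# canonical status
CANONICAL_MATERNAL = "canonical_maternal"
CANONICAL_PATERNAL = "canonical_paternal"
NON_CANONICAL = "non_canonical"
NOT_APPLICABLE = "not_applicable"

RATIO_BAND_DEFAULT = (0.35, 0.65)


@dataclass
class ImprintCall:
    region_id: str
    consensus_class: str
    canonical_status: str = NOT_APPLICABLE
    assigned_gene: str | None = None
    promoter_overlap: bool = False
    noncanonical_direction_flag: str = ""  # "maternal" for flagged maternal NC calls
    evidence: dict = field(default_factory=dict)  # cross -> BiasResult


def _direction_to_strain(direction: str, cross: str) -> str:
    """Map a parental direction to the favored strain for a given cross."""
    maternal_is_b6 = cross.startswith("B6")
    if direction == "maternal":
        return "B6" if maternal_is_b6 else "CAST"
    return "CAST" if maternal_is_b6 else "B6"


def classify_reciprocal(bias_cross1: dict | list, bias_cross2: dict | list,
                        cross1: str = "B6/CAST", cross2: str = "CAST/B6"
                        ) -> list[ImprintCall]:
    """Consensus classification of every region tested in both crosses.

    Significant in both crosses with the same parental direction ->
    imprinted; same strain direction (parental direction switches) ->
    strain-specific; exactly one cross -> single_cross_only; neither ->
    biallelic.  Regions missing from either cross are unresolved.
    """
    by1 = {r.region_id: r for r in bias_cross1} if not isinstance(bias_cross1, dict) else bias_cross1
    by2 = {r.region_id: r for r in bias_cross2} if not isinstance(bias_cross2, dict) else bias_cross2
    calls = []
    for rid in list(dict.fromkeys(list(by1) + list(by2))):
        r1, r2 = by1.get(rid), by2.get(rid)
        if r1 is None or r2 is None:
            logger.info("region %s missing from one cross: unresolved", rid)
            calls.append(ImprintCall(rid, UNRESOLVED))
            continue
        evidence = {cross1: r1, cross2: r2}
        if r1.significant and r2.significant:
            if r1.direction == r2.direction:
                cls = (IMPRINTED_MATERNAL if r1.direction == "maternal"
                       else IMPRINTED_PATERNAL)
            else:
                # directions switched between crosses: the bias tracks a
                # strain, and both orientations agree on which one
                strain = _direction_to_strain(r1.direction, cross1)
                cls = STRAIN_B6 if strain == "B6" else STRAIN_CAST
        elif r1.significant or r2.significant:
            cls = SINGLE_CROSS_ONLY
        else:
            cls = BIALLELIC
        calls.append(ImprintCall(rid, cls, evidence=evidence))
    return calls


def classify_canonical(imprint_calls: list[ImprintCall],
                       bias_matdko: dict | list,
                       gdmr_regions: list[GenomicInterval] | None = None,
                       region_intervals: dict | None = None,
                       matdko_ratios: dict | None = None,
                       ratio_band: tuple[float, float] = RATIO_BAND_DEFAULT
                       ) -> list[ImprintCall]:
    """Canonical vs non-canonical status for imprinted regions.

    Not significant in matDKO AND matDKO allelic ratio inside
    ``ratio_band`` -> canonical_maternal (germline-DMR dependent).
    Still significant with the same parental direction -> canonical_paternal
    if the region overlaps a known paternal gDMR, else non_canonical.
    Regions without matDKO data (or outside both rules) -> unresolved.
    """
    by_dko = ({r.region_id: r for r in bias_matdko}
              if not isinstance(bias_matdko, dict) else bias_matdko)
    gdmr_regions = gdmr_regions or []
    lo, hi = ratio_band
    for call in imprint_calls:
        if call.consensus_class not in IMPRINTED_CLASSES:
            raise ValueError(
                f"classify_canonical got non-imprinted region {call.region_id}")
        dko = by_dko.get(call.region_id)
        if dko is None:
            call.canonical_status = UNRESOLVED
            continue
        call.evidence["matDKO/CAST"] = dko
        if matdko_ratios is not None and call.region_id in matdko_ratios:
            ratio = matdko_ratios[call.region_id]
        else:
            total = dko.mat + dko.pat
            ratio = dko.mat / total if total else float("nan")
        parental_dir = ("maternal" if call.consensus_class == IMPRINTED_MATERNAL
                        else "paternal")
        if not dko.significant and lo <= ratio <= hi:
            call.canonical_status = CANONICAL_MATERNAL
        elif dko.significant and dko.direction == parental_dir:
            overlaps_gdmr = False
            if region_intervals is not None:
                iv = region_intervals.get(call.region_id)
                overlaps_gdmr = iv is not None and any(
                    iv.overlaps(g) for g in gdmr_regions)
            call.canonical_status = (CANONICAL_PATERNAL if overlaps_gdmr
                                     else NON_CANONICAL)
            if call.canonical_status == NON_CANONICAL and parental_dir == "maternal":
                # maternal-direction non-canonical calls are emitted but
                # flagged; downstream feature analyses use paternal ones
                call.noncanonical_direction_flag = "maternal"
        else:
            call.canonical_status = UNRESOLVED
    return imprint_calls


# ---------------------------------------------------------------------------
# Peak-to-gene assignment
# ---------------------------------------------------------------------------

def promoter_interval(gene: Gene, upstream: int = 1000, downstream: int = 500
                      ) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS."""
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    return GenomicInterval(gene.interval.chrom, max(0, start), end, gene.strand)


def _distance(iv: GenomicInterval, gene: Gene) -> int:
    """Distance in bp from an interval to a gene (0 if overlapping)."""
    if iv.chrom != gene.interval.chrom:
        return 10 ** 12
    g = gene.interval
    if iv.overlaps(g):
        return 0
    gap_body = g.start - iv.end + 1 if iv.end <= g.start else iv.start - g.end + 1
    gap_tss = min(abs(gene.tss - (iv.end - 1)), abs(gene.tss - iv.start))
    if iv.contains(iv.chrom, gene.tss):
        gap_tss = 0
    return min(max(gap_body, 0), gap_tss)


def assign_peak_to_gene(peak: Peak, genes: list[Gene],
                        promoter_upstream: int = 1000,
                        promoter_downstream: int = 500,
                        max_distance: int = 10_000) -> list[tuple[Gene, bool]]:
    """Assign a peak to genes: promoter overlap first, else nearest in 10 kb.

    Returns (gene, promoter_overlap) pairs: all genes whose promoter
    window the peak overlaps, or the single nearest gene within
    ``max_distance``, or an empty list.  Nearest-gene ties break by
    distance then lexicographic gene id.
    """
    promoter_hits = []
    for gene in genes:
        if peak.interval.overlaps(promoter_interval(gene, promoter_upstream,
                                                    promoter_downstream)):
            promoter_hits.append((gene, True))
    if promoter_hits:
        return sorted(promoter_hits, key=lambda gb: gb[0].id)
    candidates = sorted(
        ((d, gene) for gene in genes
         if (d := _distance(peak.interval, gene)) <= max_distance),
        key=lambda dg: (dg[0], dg[1].id))
    if candidates:
        return [(candidates[0][1], False)]
    return []


# ---------------------------------------------------------------------------
# Expression cross-validation
# ---------------------------------------------------------------------------

def cross_validate_expression(imprinted_calls: list[ImprintCall],
                              auxiliary_results: dict,
                              informative_by_dataset: dict
                              ) -> tuple[pd.DataFrame, float]:
    """Validate imprinted peaks against allelic expression of their genes.

    ``auxiliary_results`` maps dataset name -> {gene_id: BiasResult}
    (H3K36me3, RNA-seq ...); ``informative_by_dataset`` maps dataset name
    -> set of gene ids passing that dataset's read filter.  A gene
    validates when at least one informative dataset shows a significant
    bias in the same parental direction as the peak; genes uninformative
    in every dataset are excluded from the denominator.
    Returns (per-gene table, validated / informative fraction).
    """
    if not auxiliary_results:
        raise ValueError("no auxiliary datasets supplied")
    rows = []
    n_informative = n_validated = 0
    for call in imprinted_calls:
        if call.consensus_class not in IMPRINTED_CLASSES or call.assigned_gene is None:
            continue
        gene_id = call.assigned_gene
        parental_dir = ("maternal" if call.consensus_class == IMPRINTED_MATERNAL
                        else "paternal")
        informative_in = [ds for ds, ids in informative_by_dataset.items()
                          if gene_id in ids]
        validated = any(
            (res := auxiliary_results[ds].get(gene_id)) is not None
            and res.significant and res.direction == parental_dir
            for ds in informative_in)
        if informative_in:
            n_informative += 1
            n_validated += int(validated)
        rows.append({"region_id": call.region_id, "gene_id": gene_id,
                     "direction": parental_dir,
                     "informative": bool(informative_in),
                     "validated": bool(validated) if informative_in else None})
    fraction = n_validated / n_informative if n_informative else float("nan")
    return pd.DataFrame(rows), fraction


def calls_to_frame(calls: list[ImprintCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "region_id": c.region_id, "consensus_class": c.consensus_class,
            "canonical_status": c.canonical_status,
            "assigned_gene": c.assigned_gene or "",
            "promoter_overlap": c.promoter_overlap,
            "noncanonical_direction_flag": c.noncanonical_direction_flag,
        })
    return pd.DataFrame(rows)
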