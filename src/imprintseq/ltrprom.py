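"""ERVK LTR promoter discovery from spliced RNA evidence.

An LTR is called a transcriptionally active promoter when four
conjunctive criteria hold: (a) it lies within an H3K4me3 peak; (b) at
least ``min_reads`` same-strand reads overlap it in at least
``min_replicates`` replicates (replicates may pool across tissues);
(c) at least one splice-junction read has its donor inside the LTR
(spliced RNA initiating there); and (d) no junction read splices INTO
the LTR from upstream on the transcript strand — an incoming acceptor
marks run-through transcription, not initiation.

Active promoters are typed as chimeric mRNA when a junction links the
LTR donor to an annotated exon of a same-strand gene (the lowest-index
exon hit in transcription order is reported, typically exon 2), else as
non-coding RNA.

Junction tuples are genomic (left, right): on a + strand transcript the
biological donor is the left coordinate and the acceptor the right; on
a - strand transcript the roles swap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .biastest import allelic_bias_test
from .core_io import Gene, Peak, ReadRecord, RepeatElement

logger = logging.getLogger("imprintseq")

MIN_READS_DEFAULT = 5
MIN_REPLICATES_DEFAULT = 2
MIN_SNP_READS_DEFAULT = 5  # informativeness floor for allelic expression


@dataclass
class LtrPromoterCall:
    ltr_id: str
    in_h3k4me3_peak: bool
    peak_id: str | None
    same_strand_read_counts: dict  # (sample_id, replicate) -> count
    n_intron_spanning_from_ltr: int
    n_upstream_junctions_into_ltr: int
    is_active_promoter: bool
    transcript_type: str = "none"  # chimera / ncRNA / none
    chimera_gene: str | None = None
    chimera_exon_index: int | None = None
    imprint_context: str = "no_peak"  # non_canonical_paternal_peak/other_peak/no_peak
    strand_used: str = "."
    strand_flagged: bool = False


def _junction_roles(junction: tuple[int, int], strand: str) -> tuple[int, int]:
    """(biological donor, biological acceptor) genomic coordinates."""
    left, right = junction
    return (left, right) if strand == "+" else (right, left)


def _evaluate_strand(ltr: RepeatElement, reads: list[ReadRecord], strand: str,
                     min_reads: int, min_replicates: int) -> dict:
    iv = ltr.interval
    per_rep: dict[tuple, int] = {}
    n_donor = n_incoming = 0
    for read in reads:
        if read.chrom != iv.chrom or read.strand != strand:
            continue
        overlaps = read.start < iv.end and iv.start < read.end
        if overlaps:
            key = (read.sample_id, read.replicate)
            per_rep[key] = per_rep.get(key, 0) + 1
        for junction in read.junctions:
            donor, acceptor = _junction_roles(junction, strand)
            if iv.start <= donor < iv.end:
                n_donor += 1
            if iv.start <= acceptor < iv.end or acceptor == iv.end:
                # acceptor inside the LTR with the donor upstream of it on
                # the transcript strand: run-through transcription
                upstream = (donor < iv.start) if strand == "+" else (donor >= iv.end)
                if upstream:
                    n_incoming += 1
    n_supported = sum(1 for c in per_rep.values() if c >= min_reads)
    return {
        "per_rep": per_rep, "n_donor": n_donor, "n_incoming": n_incoming,
        "n_supported_reps": n_supported,
        "reads_ok": n_supported >= min_replicates,
    }


def identify_active_ltr_promoters(ltrs: list[RepeatElement], peaks: list[Peak],
                                  reads: list[ReadRecord],
                                  min_reads: int = MIN_READS_DEFAULT,
                                  min_replicates: int = MIN_REPLICATES_DEFAULT,
                                  peak_context: dict | None = None
                                  ) -> list[LtrPromoterCall]:
    """Apply the four-criterion promoter filter cascade to every LTR.

    ``peak_context`` optionally maps peak id -> imprint context label
    ("non_canonical_paternal_peak" / "other_peak") to partition calls.
    Reads must be stranded; each (sample, replicate) pair counts as one
    replicate toward the support rule, pooling tissues/datasets.
    """
    if any(r.strand not in "+-" for r in reads):
        raise ValueError("unstranded reads are not allowed")
    calls = []
    for ltr in ltrs:
        peak_hit = next((p for p in peaks if p.interval.overlaps(ltr.interval)), None)
        if ltr.strand in "+-":
            strand, flagged = ltr.strand, False
            ev = _evaluate_strand(ltr, reads, strand, min_reads, min_replicates)
        else:
            # unstranded annotation: test both strands, take the better
            ev_by = {s: _evaluate_strand(ltr, reads, s, min_reads, min_replicates)
                     for s in "+-"}
            strand = max("+-", key=lambda s: sum(ev_by[s]["per_rep"].values()))
            ev = ev_by[strand]
            flagged = True
        active = (peak_hit is not None and ev["reads_ok"]
                  and ev["n_donor"] >= 1 and ev["n_incoming"] == 0)
        context = "no_peak"
        if peak_hit is not None:
            context = (peak_context or {}).get(peak_hit.id, "other_peak")
        calls.append(LtrPromoterCall(
            ltr_id=ltr.repeat_name,
            in_h3k4me3_peak=peak_hit is not None,
            peak_id=peak_hit.id if peak_hit else None,
            same_strand_read_counts=ev["per_rep"],
            n_intron_spanning_from_ltr=ev["n_donor"],
            n_upstream_junctions_into_ltr=ev["n_incoming"],
            is_active_promoter=bool(active),
            imprint_context=context,
            strand_used=strand,
            strand_flagged=flagged,
        ))
    return calls


def type_transcript(call: LtrPromoterCall, ltr: RepeatElement,
                    reads: list[ReadRecord], genes: list[Gene]
                    ) -> LtrPromoterCall:
    """Type an active promoter call as chimeric mRNA or ncRNA.

    Chimera: some junction read links the LTR donor to an annotated exon
    of a same-strand gene; the reported target is the gene and the
    lowest-index exon hit in transcription order.  Everything else
    (junctions to unannotated positions or opposite-strand exons) is
    ncRNA.
    """
    if not call.is_active_promoter:
        raise ValueError("type_transcript requires an active promoter call")
    iv = ltr.interval
    strand = call.strand_used
    best: tuple[int, str] | None = None
    for read in reads:
        if read.chrom != iv.chrom or read.strand != strand:
            continue
        for junction in read.junctions:
            donor, acceptor = _junction_roles(junction, strand)
            if not (iv.start <= donor < iv.end):
                continue
            for gene in genes:
                if gene.strand != strand or gene.interval.chrom != iv.chrom:
                    continue
                for idx, exon in enumerate(gene.exons_in_transcription_order(),
                                           start=1):
                    in_exon = (exon.start <= acceptor < exon.end
                               if strand == "+"
                               else exon.start < acceptor <= exon.end)
                    if in_exon and (best is None or idx < best[0]):
                        best = (idx, gene.id)
    if best is not None:
        call.transcript_type = "chimera"
        call.chimera_exon_index, call.chimera_gene = best
    else:
        call.transcript_type = "ncRNA"
    return call


def ltr_allelic_expression(calls: list[LtrPromoterCall],
                           ltrs_by_id: dict,
                           partition_by_allele: dict,
                           rho: float = 0.0, cross: str = "",
                           min_snp_reads: int = MIN_SNP_READS_DEFAULT
                           ) -> pd.DataFrame:
    """Strand-aware allelic counts and bias tests over active LTRs.

    ``partition_by_allele`` maps maternal/paternal to allele-assigned
    read lists (SNP-spanning by construction).  LTRs with fewer than
    ``min_snp_reads`` allelic reads in every replicate are reported
    uninformative and left untested.
    """
    rows = []
    for call in calls:
        if not call.is_active_promoter:
            continue
        ltr = ltrs_by_id[call.ltr_id]
        iv = ltr.interval
        per_rep: dict[tuple, dict] = {}
        for allele in ("maternal", "paternal"):
            for read in partition_by_allele.get(allele, []):
                if (read.chrom == iv.chrom and read.strand == call.strand_used
                        and read.start < iv.end and iv.start < read.end):
                    key = (read.sample_id, read.replicate)
                    per_rep.setdefault(key, {"mat": 0, "pat": 0})
                    per_rep[key]["mat" if allele == "maternal" else "pat"] += 1
        informative = any(v["mat"] + v["pat"] >= min_snp_reads
                          for v in per_rep.values())
        for (sample_id, replicate), v in sorted(per_rep.items()):
            rows.append({"region_id": call.ltr_id, "sample_id": sample_id,
                         "replicate": replicate, "mat": v["mat"], "pat": v["pat"],
                         "unassigned": 0, "region_kind": "ltr",
                         "informative": informative})
        if not per_rep:
            rows.append({"region_id": call.ltr_id, "sample_id": "", "replicate": 1,
                         "mat": 0, "pat": 0, "unassigned": 0,
                         "region_kind": "ltr", "informative": False})
    counts = pd.DataFrame(rows)
    if counts.empty:
        return counts
    testable = counts[counts["informative"]]
    results = allelic_bias_test(
        testable[["region_id", "sample_id", "replicate", "mat", "pat"]],
        rho=rho, cross=cross)
    by_id = {r.region_id: r for r in results}
    summary = []
    for ltr_id, grp in counts.groupby("region_id", sort=False):
        res = by_id.get(ltr_id)
        summary.append({
            "ltr_id": ltr_id, "informative": bool(grp["informative"].any()),
            "mat": int(grp["mat"].sum()), "pat": int(grp["pat"].sum()),
            "p_value": res.p_value if res else float("nan"),
            "q_value": res.q_value if res else float("nan"),
            "significant": res.significant if res else False,
            "direction": res.direction if res else "none",
        })
    return pd.DataFrame(summary)


def promoter_calls_to_frame(calls: list[LtrPromoterCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "ltr_id": c.ltr_id, "in_h3k4me3_peak": c.in_h3k4me3_peak,
            "peak_id": c.peak_id or "",
            "n_supported_replicates": sum(
                1 for v in c.same_strand_read_counts.values() if v >= MIN_READS_DEFAULT),
            "n_intron_spanning_from_ltr": c.n_intron_spanning_from_ltr,
            "n_upstream_junctions_into_ltr": c.n_upstream_junctions_into_ltr,
            "is_active_promoter": c.is_active_promoter,
            "transcript_type": c.transcript_type,
            "chimera_gene": c.chimera_gene or "",
            "chimera_exon_index": c.chimera_exon_index or 0,
            "imprint_context": c.imprint_context,
        })
    return pd.DataFrame(rows)
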