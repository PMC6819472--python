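"""SNP-based assignment of reads to parental genomes.

A read is sorted into genome1, genome2 or unassigned from the bases it
shows at known strain-discriminating SNP positions: it is called for a
genome only if every informative observation matches that genome and at
least one SNP was overlapped.  A base matching neither genome counts as
a conflict (unassigned), not as a missing observation — the conservative
reading of a three-way sort.  Observations at positions absent from the
SNP table are ignored and logged.

The two-pass scheme handles the admixed matDKO maternal genome (~85% B6,
~15% 129): pass 1 sorts against a B6/CAST table from which positions
where 129 and CAST share the alternate base have been excluded; reads
left unassigned are re-sorted against a 129/CAST table, and 129 calls
join the maternal set while CAST calls from either pass form the
paternal set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_io import CrossDesign, ReadRecord, SNPRecord

logger = logging.getLogger("imprintseq")

GENOME1 = "genome1"
GENOME2 = "genome2"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlleleAssignment:
    read_id: str
    call: str
    n_snps_overlapped: int
    n_matching_g1: int
    n_matching_g2: int

    def __post_init__(self) -> None:
        if self.n_matching_g1 + self.n_matching_g2 > self.n_snps_overlapped:
            raise ValueError("matches exceed overlapped SNPs")


def build_snp_index(snps: list[SNPRecord]) -> dict:
    """Queryable (chrom, pos) -> SNPRecord index."""
    return {(s.chrom, s.pos): s for s in snps}


def assign_read(read: ReadRecord, snp_index: dict) -> AlleleAssignment:
    """Three-way sort of one read against a SNP index."""
    n_overlap = n_g1 = n_g2 = 0
    for pos, base in read.snp_obs:
        snp = snp_index.get((read.chrom, pos))
        if snp is None:
            logger.debug("read %s: observation at %s:%d not in SNP table, ignored",
                         read.read_id, read.chrom, pos)
            continue
        n_overlap += 1
        if base == snp.base_genome1:
            n_g1 += 1
        elif base == snp.base_genome2:
            n_g2 += 1
        # else: matches neither genome -> conflict, counted in n_overlap only
    if n_overlap > 0 and n_g1 == n_overlap:
        call = GENOME1
    elif n_overlap > 0 and n_g2 == n_overlap:
        call = GENOME2
    else:
        call = UNASSIGNED
    return AlleleAssignment(read.read_id, call, n_overlap, n_g1, n_g2)


@dataclass
class ReadPartition:
    """Parental partition of a read set (sizes sum to the input size)."""

    maternal: list
    paternal: list
    unassigned: list

    def __len__(self) -> int:
        return len(self.maternal) + len(self.paternal) + len(self.unassigned)

    def summary(self) -> dict:
        return {"maternal": len(self.maternal), "paternal": len(self.paternal),
                "unassigned": len(self.unassigned)}


def split_reads(reads: list[ReadRecord], snp_index: dict,
                cross: CrossDesign | str) -> ReadPartition:
    """Partition reads into maternal/paternal/unassigned for one cross.

    Genome1 is B6 and genome2 is CAST in the SNP table; the cross
    orientation decides which is maternal.
    """
    if isinstance(cross, CrossDesign):
        maternal_strain = cross.maternal_strain
    else:
        maternal_strain = cross.split("/")[0].replace("matDKO", "B6_129")
    genome1_is_maternal = maternal_strain in ("B6", "B6_129")
    mat, pat, una = [], [], []
    for read in reads:
        call = assign_read(read, snp_index).call
        if call == UNASSIGNED:
            una.append(read)
        elif (call == GENOME1) == genome1_is_maternal:
            mat.append(read)
        else:
            pat.append(read)
    return ReadPartition(mat, pat, una)


def two_pass_maternal_assignment(reads: list[ReadRecord],
                                 snps_b6_cast_excl_shared: dict | list,
                                 snps_129_cast: dict | list) -> ReadPartition:
    """Two-pass matDKO read sorting for the admixed B6/129 maternal genome.

    Pass 1 sorts against B6 (genome1) vs CAST (genome2) with 129/CAST-shared
    positions excluded; B6 calls are maternal.  Reads unassigned in pass 1
    are re-sorted against 129 (genome1) vs CAST (genome2); 129 calls join
    the maternal set and CAST calls from either pass the paternal set.
    Reads assigned in pass 1 are never revisited (idempotence).
    """
    if snps_129_cast is None:
        raise ValueError("two-pass assignment requires the 129/CAST SNP table")
    idx1 = (snps_b6_cast_excl_shared
            if isinstance(snps_b6_cast_excl_shared, dict)
            else build_snp_index(snps_b6_cast_excl_shared))
    idx2 = (snps_129_cast if isinstance(snps_129_cast, dict)
            else build_snp_index(snps_129_cast))
    mat, pat, una = [], [], []
    for read in reads:
        call = assign_read(read, idx1).call
        if call == GENOME1:
            mat.append(read)
        elif call == GENOME2:
            pat.append(read)
        else:
            call2 = assign_read(read, idx2).call
            if call2 == GENOME1:
                mat.append(read)
            elif call2 == GENOME2:
                pat.append(read)
            else:
                una.append(read)
    return ReadPartition(mat, pat, una)
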