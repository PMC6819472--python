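"""LTR promoter filter cascade and transcript typing."""

import pytest

from imprintseq import ltrprom
from imprintseq.core_io import Gene, GenomicInterval, Peak, ReadRecord, RepeatElement
from imprintseq.ltrprom import identify_active_ltr_promoters, type_transcript


LTR = RepeatElement(GenomicInterval("chr1", 10_000, 10_400, "+"),
                    "RLTR15", "LTR", "ERVK")
PEAK = Peak("pk", GenomicInterval("chr1", 9_900, 10_900))
DONOR_JX = (10_300, 15_000)  # donor inside the LTR
INCOMING_JX = (9_000, 10_100)  # acceptor inside the LTR, donor upstream


def reads_over_ltr(n, replicate, strand="+", junctions=(), sample="s"):
    return [ReadRecord(f"r{replicate}_{i}", "chr1", 10_050, 10_150, strand,
                       (), junctions if i == 0 else (), sample, replicate)
            for i in range(n)]


class TestPromoterCriteria:
    def test_all_criteria_met_is_active(self):
        reads = (reads_over_ltr(6, 1, junctions=(DONOR_JX,))
                 + reads_over_ltr(6, 2))
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert call.is_active_promoter

    def test_second_replicate_below_threshold_fails(self):
        reads = (reads_over_ltr(6, 1, junctions=(DONOR_JX,))
                 + reads_over_ltr(4, 2))
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert not call.is_active_promoter

    def test_no_peak_overlap_fails(self):
        reads = reads_over_ltr(6, 1, junctions=(DONOR_JX,)) + reads_over_ltr(6, 2)
        far_peak = Peak("pk", GenomicInterval("chr1", 50_000, 51_000))
        [call] = identify_active_ltr_promoters([LTR], [far_peak], reads)
        assert not call.is_active_promoter and not call.in_h3k4me3_peak

    def test_no_donor_junction_fails(self):
        reads = reads_over_ltr(6, 1) + reads_over_ltr(6, 2)
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert not call.is_active_promoter
        assert call.n_intron_spanning_from_ltr == 0

    def test_incoming_upstream_junction_vetoes(self):
        reads = (reads_over_ltr(6, 1, junctions=(DONOR_JX,))
                 + reads_over_ltr(6, 2, junctions=(INCOMING_JX,)))
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert not call.is_active_promoter
        assert call.n_upstream_junctions_into_ltr == 1

    def test_opposite_strand_reads_do_not_count(self):
        reads = (reads_over_ltr(6, 1, strand="-", junctions=(DONOR_JX,))
                 + reads_over_ltr(6, 2, strand="-"))
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert not call.is_active_promoter

    def test_replicates_pool_across_samples(self):
        reads = (reads_over_ltr(6, 1, sample="tissueA", junctions=(DONOR_JX,))
                 + reads_over_ltr(6, 1, sample="tissueB"))
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert call.is_active_promoter

    def test_minus_strand_donor_detection(self):
        minus_ltr = RepeatElement(GenomicInterval("chr1", 10_000, 10_400, "-"),
                                  "L2", "LTR", "ERVK")
        jx = (5_000, 10_300)  # right coordinate = biological donor on '-'
        reads = [ReadRecord(f"r{rep}_{i}", "chr1", 10_050, 10_150, "-",
                            (), (jx,) if i == 0 else (), "s", rep)
                 for rep in (1, 2) for i in range(6)]
        [call] = identify_active_ltr_promoters([minus_ltr], [PEAK], reads)
        assert call.is_active_promoter


GENE = Gene("g1", "Gab1", GenomicInterval("chr1", 14_000, 20_000, "+"), "+",
            14_000,
            (GenomicInterval("chr1", 14_000, 14_200, "+"),
             GenomicInterval("chr1", 15_000, 15_300, "+"),
             GenomicInterval("chr1", 18_000, 18_300, "+")))


class TestTranscriptTyping:
    def _active_call(self, reads):
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        assert call.is_active_promoter
        return call

    def test_junction_onto_exon2_is_chimera(self):
        reads = (reads_over_ltr(6, 1, junctions=((10_300, 15_000),))
                 + reads_over_ltr(6, 2))
        call = self._active_call(reads)
        type_transcript(call, LTR, reads, [GENE])
        assert call.transcript_type == "chimera"
        assert call.chimera_gene == "g1" and call.chimera_exon_index == 2

    def test_unannotated_acceptor_is_ncrna(self):
        reads = (reads_over_ltr(6, 1, junctions=((10_300, 30_000),))
                 + reads_over_ltr(6, 2))
        call = self._active_call(reads)
        type_transcript(call, LTR, reads, [GENE])
        assert call.transcript_type == "ncRNA"

    def test_opposite_strand_exon_is_ncrna(self):
        minus_gene = Gene("g2", "G2", GenomicInterval("chr1", 14_000, 20_000, "-"),
                          "-", 19_999,
                          (GenomicInterval("chr1", 14_000, 14_200, "-"),
                           GenomicInterval("chr1", 15_000, 15_300, "-")))
        reads = (reads_over_ltr(6, 1, junctions=((10_300, 15_000),))
                 + reads_over_ltr(6, 2))
        call = self._active_call(reads)
        type_transcript(call, LTR, reads, [minus_gene])
        assert call.transcript_type == "ncRNA"

    def test_inactive_call_rejected(self):
        [call] = identify_active_ltr_promoters([LTR], [PEAK], [])
        with pytest.raises(ValueError):
            type_transcript(call, LTR, [], [GENE])


class TestAllelicExpression:
    def _call(self):
        reads = (reads_over_ltr(6, 1, junctions=(DONOR_JX,))
                 + reads_over_ltr(6, 2))
        [call] = identify_active_ltr_promoters([LTR], [PEAK], reads)
        return call

    def test_below_snp_read_floor_is_uninformative(self):
        call = self._call()
        part = {"maternal": reads_over_ltr(2, 1), "paternal": reads_over_ltr(2, 2)}
        out = ltrprom.ltr_allelic_expression([call], {"RLTR15": LTR}, part)
        assert not out.iloc[0]["informative"]

    def test_paternal_skew_detected(self):
        call = self._call()
        pat = [ReadRecord(f"p{i}", "chr1", 10_050, 10_150, "+", (), (), "s", 1)
               for i in range(40)]
        mat = [ReadRecord(f"m{i}", "chr1", 10_050, 10_150, "+", (), (), "s", 1)
               for i in range(2)]
        out = ltrprom.ltr_allelic_expression([call], {"RLTR15": LTR},
                                             {"maternal": mat, "paternal": pat})
        row = out.iloc[0]
        assert row["informative"] and row["significant"]
        assert row["direction"] == "paternal"

    def test_end_to_end_planted_promoters_recovered(self, default_study,
                                                    default_bundle):
        """On the default simulation the active set equals the planted set
        and every chimera target matches its planted partner gene."""
        _data, truth = default_study
        planted = set(truth.loc[truth["is_ltr_promoter"], "ltr_id"])
        called = {c.ltr_id for c in default_bundle.ltr_promoter_calls
                  if c.is_active_promoter}
        assert called == planted
        by_ltr = {c.ltr_id: c for c in default_bundle.ltr_promoter_calls}
        for row in truth[truth["transcript_type"] == "chimera"].itertuples():
            call = by_ltr[row.ltr_id]
            assert call.transcript_type == "chimera"
            assert call.chimera_gene == row.chimera_partner_gene
        for row in truth[truth["transcript_type"] == "ncRNA"].itertuples():
            assert by_ltr[row.ltr_id].transcript_type == "ncRNA"
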