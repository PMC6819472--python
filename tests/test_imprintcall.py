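"""Reciprocal-cross and matDKO classification logic."""

import pandas as pd
import pytest

from imprintseq import imprintcall
from imprintseq.biastest import BiasResult
from imprintseq.core_io import Gene, GenomicInterval, Peak
from imprintseq.imprintcall import (
    ImprintCall,
    assign_peak_to_gene,
    classify_canonical,
    classify_reciprocal,
    cross_validate_expression,
)


def bias(rid, significant, direction, mat=90, pat=10, cross=""):
    if not significant:
        direction = "none"
        mat = pat = 50
    elif direction == "paternal":
        mat, pat = pat, mat
    return BiasResult(rid, cross, mat, pat, 0.0, 0.001 if significant else 0.8,
                      0.004 if significant else 0.9, significant, direction,
                      2, mat + pat)


class TestClassifyReciprocal:
    def test_consistent_parental_direction_is_imprinted(self):
        calls = classify_reciprocal([bias("r", True, "maternal")],
                                    [bias("r", True, "maternal")])
        assert calls[0].consensus_class == imprintcall.IMPRINTED_MATERNAL

    def test_switched_direction_is_strain_specific(self):
        # B6-favoring: maternal in B6/CAST, paternal in CAST/B6
        calls = classify_reciprocal([bias("r", True, "maternal")],
                                    [bias("r", True, "paternal")])
        assert calls[0].consensus_class == imprintcall.STRAIN_B6
        calls = classify_reciprocal([bias("r", True, "paternal")],
                                    [bias("r", True, "maternal")])
        assert calls[0].consensus_class == imprintcall.STRAIN_CAST

    def test_single_cross_excluded_from_consensus(self):
        calls = classify_reciprocal([bias("r", True, "maternal")],
                                    [bias("r", False, "none")])
        assert calls[0].consensus_class == imprintcall.SINGLE_CROSS_ONLY

    def test_neither_significant_is_biallelic(self):
        calls = classify_reciprocal([bias("r", False, "none")],
                                    [bias("r", False, "none")])
        assert calls[0].consensus_class == imprintcall.BIALLELIC

    def test_missing_region_unresolved(self):
        calls = classify_reciprocal([bias("r", True, "maternal")], [])
        assert calls[0].consensus_class == imprintcall.UNRESOLVED

    def test_relabeling_crosses_swaps_strain_fixes_imprints(self):
        """Reciprocal symmetry: swapping the cross labels preserves
        imprint calls and swaps the strain attribution."""
        r1 = [bias("imp", True, "paternal"), bias("str", True, "maternal")]
        r2 = [bias("imp", True, "paternal"), bias("str", True, "paternal")]
        fwd = {c.region_id: c.consensus_class for c in classify_reciprocal(
            r1, r2, "B6/CAST", "CAST/B6")}
        rev = {c.region_id: c.consensus_class for c in classify_reciprocal(
            r2, r1, "CAST/B6", "B6/CAST")}
        assert fwd["imp"] == rev["imp"] == imprintcall.IMPRINTED_PATERNAL
        assert fwd["str"] == imprintcall.STRAIN_B6
        assert rev["str"] == imprintcall.STRAIN_B6

    def test_no_region_gets_both_strain_and_imprint_label(self):
        for d1 in ("maternal", "paternal"):
            for d2 in ("maternal", "paternal"):
                cls = classify_reciprocal([bias("r", True, d1)],
                                          [bias("r", True, d2)])[0].consensus_class
                assert (cls.startswith("strain")) != (cls.startswith("imprinted"))


class TestClassifyCanonical:
    def _imprinted(self, rid="r", cls=imprintcall.IMPRINTED_PATERNAL):
        return ImprintCall(rid, cls)

    def test_retained_bias_without_gdmr_is_noncanonical(self):
        calls = classify_canonical([self._imprinted()],
                                   [bias("r", True, "paternal")])
        assert calls[0].canonical_status == imprintcall.NON_CANONICAL

    def test_lost_bias_is_canonical_maternal(self):
        dko = bias("r", False, "none")  # ratio 0.5 from 50/50 counts
        calls = classify_canonical([self._imprinted()], [dko])
        assert calls[0].canonical_status == imprintcall.CANONICAL_MATERNAL

    def test_retained_bias_at_paternal_gdmr_is_canonical_paternal(self):
        iv = GenomicInterval("chr1", 100, 200)
        calls = classify_canonical(
            [self._imprinted()], [bias("r", True, "paternal")],
            gdmr_regions=[GenomicInterval("chr1", 150, 300)],
            region_intervals={"r": iv})
        assert calls[0].canonical_status == imprintcall.CANONICAL_PATERNAL

    def test_nonsignificant_but_skewed_ratio_is_unresolved(self):
        """A ratio outside the balance band blocks the canonical call:
        power loss must not masquerade as loss of imprinting."""
        calls = classify_canonical([self._imprinted()],
                                   [bias("r", False, "none")],
                                   matdko_ratios={"r": 0.75})
        assert calls[0].canonical_status == imprintcall.UNRESOLVED

    def test_missing_matdko_data_unresolved(self):
        calls = classify_canonical([self._imprinted()], [])
        assert calls[0].canonical_status == imprintcall.UNRESOLVED

    def test_non_imprinted_region_rejected(self):
        with pytest.raises(ValueError):
            classify_canonical([ImprintCall("r", imprintcall.BIALLELIC)], [])

    def test_maternal_noncanonical_flagged(self):
        calls = classify_canonical(
            [self._imprinted(cls=imprintcall.IMPRINTED_MATERNAL)],
            [bias("r", True, "maternal")])
        assert calls[0].canonical_status == imprintcall.NON_CANONICAL
        assert calls[0].noncanonical_direction_flag == "maternal"


def _gene(gid, tss, strand="+", chrom="chr1", body=5000):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + body, strand)
    else:
        iv = GenomicInterval(chrom, tss - body + 1, tss + 1, strand)
    return Gene(gid, gid, iv, strand, tss)


class TestAssignPeakToGene:
    def test_peak_spanning_tss_is_promoter_overlap(self):
        gene = _gene("g1", 5000)
        peak = Peak("p", GenomicInterval("chr1", 4800, 5200))
        [(hit, promoter)] = assign_peak_to_gene(peak, [gene])
        assert hit.id == "g1" and promoter

    def test_nearby_peak_assigned_without_promoter_flag(self):
        gene = _gene("g1", 50_000)
        peak = Peak("p", GenomicInterval("chr1", 44_000, 45_000))  # 4 kb away
        [(hit, promoter)] = assign_peak_to_gene(peak, [gene])
        assert hit.id == "g1" and not promoter

    def test_distant_peak_unassigned(self):
        gene = _gene("g1", 100_000)
        peak = Peak("p", GenomicInterval("chr1", 50_000, 51_000))
        assert assign_peak_to_gene(peak, [gene]) == []

    def test_promoter_window_is_strand_oriented(self):
        minus = _gene("gm", 10_000, strand="-")
        # 800 bp upstream of a minus-strand TSS = higher coordinates
        peak = Peak("p", GenomicInterval("chr1", 10_600, 10_900))
        [(hit, promoter)] = assign_peak_to_gene(peak, [minus])
        assert promoter

    def test_multiple_promoter_overlaps_all_reported(self):
        g1, g2 = _gene("a", 5000), _gene("b", 5600)
        peak = Peak("p", GenomicInterval("chr1", 4900, 5500))
        hits = assign_peak_to_gene(peak, [g2, g1])
        assert [g.id for g, _ in hits] == ["a", "b"]


class TestCrossValidation:
    def _call(self, rid, gene, cls=imprintcall.IMPRINTED_PATERNAL):
        c = ImprintCall(rid, cls)
        c.assigned_gene = gene
        return c

    def test_same_direction_validates(self):
        aux = {"RNA": {"g1": bias("g1", True, "paternal")}}
        table, frac = cross_validate_expression(
            [self._call("p1", "g1")], aux, {"RNA": {"g1"}})
        assert frac == 1.0 and table.loc[0, "validated"]

    def test_opposite_direction_does_not_validate(self):
        aux = {"RNA": {"g1": bias("g1", True, "maternal")}}
        _table, frac = cross_validate_expression(
            [self._call("p1", "g1")], aux, {"RNA": {"g1"}})
        assert frac == 0.0

    def test_uninformative_genes_out_of_denominator(self):
        aux = {"RNA": {"g1": bias("g1", True, "paternal")}}
        _t, frac = cross_validate_expression(
            [self._call("p1", "g1"), self._call("p2", "g2")],
            aux, {"RNA": {"g1"}})
        assert frac == 1.0

    def test_no_auxiliary_data_rejected(self):
        with pytest.raises(ValueError):
            cross_validate_expression([], {}, {})
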