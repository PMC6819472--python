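"""Generator checks: determinism, planted architecture, marginal laws."""

import numpy as np
import pandas as pd
import pytest

from imprintseq import simdata
from imprintseq.simdata import (
    CLASS_BIALLELIC,
    CLASS_CANONICAL_MATERNAL,
    CLASS_NONCANONICAL,
    ConfigError,
    SimConfig,
    maternal_fraction,
    stream_rng,
)


class TestConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimConfig(class_proportions={CLASS_BIALLELIC: 0.5})

    def test_single_class_config(self):
        cfg = SimConfig(seed=3, n_chrom=1, chrom_length=3_000_000, n_peaks=100,
                        class_proportions={CLASS_BIALLELIC: 1.0})
        _ref, truth = simdata.simulate_reference(cfg)
        assert len(truth) == 100
        assert (truth["class_label"] == CLASS_BIALLELIC).all()

    def test_default_class_counts_are_exact(self, default_study):
        _data, truth = default_study
        counts = truth["class_label"].value_counts()
        assert counts[CLASS_BIALLELIC] == 700
        assert counts["strain_B6"] == 100 and counts["strain_CAST"] == 100
        assert counts[CLASS_CANONICAL_MATERNAL] == 60
        assert counts["imprinted_canonical_paternal"] == 10
        assert counts[CLASS_NONCANONICAL] == 30


class TestReference:
    def test_determinism_identical_config(self, small_config):
        ref_a, truth_a = simdata.simulate_reference(small_config)
        ref_b, truth_b = simdata.simulate_reference(small_config)
        pd.testing.assert_frame_equal(truth_a, truth_b)
        assert ref_a.snps_b6_cast == ref_b.snps_b6_cast
        assert [p.interval for p in ref_a.peaks] == [p.interval for p in ref_b.peaks]

    def test_named_streams_are_independent(self):
        a = stream_rng(0, "alpha").integers(0, 10**9)
        b = stream_rng(0, "beta").integers(0, 10**9)
        a2 = stream_rng(0, "alpha").integers(0, 10**9)
        assert a == a2 and a != b

    def test_every_noncanonical_peak_overlaps_one_ervk(self, small_study):
        data, truth = small_study
        peaks = {p.id: p for p in data.peaks}
        ervk = [r for r in data.repeats if r.repeat_family == "ERVK"]
        for row in truth[truth["class_label"] == CLASS_NONCANONICAL].itertuples():
            hits = [r for r in ervk if r.interval.overlaps(peaks[row.region_id].interval)]
            assert len(hits) == 1
            assert hits[0].repeat_name == row.ltr_id

    def test_canonical_peaks_overlap_cgis(self, small_study):
        data, truth = small_study
        peaks = {p.id: p for p in data.peaks}
        canon = truth[truth["class_label"].str.startswith("imprinted_canonical")]
        for row in canon.itertuples():
            assert any(peaks[row.region_id].interval.overlaps(c) for c in data.cgis)

    def test_ltr_lengths_near_solo_ltr_scale(self, default_study):
        data, _truth = default_study
        lengths = [len(r.interval) for r in data.repeats]
        assert 380 < np.mean(lengths) < 455

    def test_129_segment_fraction(self, small_config):
        ref, _ = simdata.simulate_reference(small_config)
        total = sum(len(seg) for seg in ref.segments_129)
        genome = sum(ref.chromosomes.values())
        assert total / genome == pytest.approx(0.15, abs=0.01)


class TestCountModel:
    def test_biallelic_binomial_mean(self):
        """At rho=0 a biallelic peak's maternal count is Binomial(n, 0.5)."""
        rng = np.random.default_rng(0)
        draws = np.array([simdata._betabinom_draw(rng, 200, 0.5, 0.0)
                          for _ in range(10_000)])
        # sample mean within 3 SD of the binomial mean n*p = 100
        assert abs(draws.mean() - 100) < 3 * np.sqrt(200 * 0.25 / 10_000)

    def test_pi_one_rho_zero_gives_zero_paternal(self):
        rng = np.random.default_rng(1)
        assert all(simdata._betabinom_draw(rng, 50, 1.0, 0.0) == 50
                   for _ in range(100))

    def test_matdko_canonical_maternal_reverts_to_balance(self):
        assert maternal_fraction(CLASS_CANONICAL_MATERNAL, "maternal",
                                 "matDKO/CAST", 0.9) == 0.5
        assert maternal_fraction(CLASS_CANONICAL_MATERNAL, "maternal",
                                 "B6/CAST", 0.9) == 0.9

    def test_noncanonical_retains_bias_in_matdko(self):
        assert maternal_fraction(CLASS_NONCANONICAL, "paternal",
                                 "matDKO/CAST", 0.9) == pytest.approx(0.1)

    def test_strain_bias_flips_between_reciprocal_crosses(self):
        f1 = maternal_fraction("strain_B6", "B6", "B6/CAST", 0.9)
        f2 = maternal_fraction("strain_B6", "B6", "CAST/B6", 0.9)
        assert f1 == pytest.approx(0.9) and f2 == pytest.approx(0.1)

    def test_unknown_cross_rejected(self, small_study):
        data, truth = small_study
        with pytest.raises(ConfigError):
            maternal_fraction(CLASS_BIALLELIC, "", "PWK/B6", 0.9)

    def test_empirical_ratio_converges_to_pi(self, default_study):
        """Planted imprints show allelic ratio near allelic_pi."""
        data, truth = default_study
        counts = data.chip_counts["B6/CAST"]
        mat_ids = set(truth.loc[
            truth["class_label"] == CLASS_CANONICAL_MATERNAL, "region_id"])
        sub = counts[counts["region_id"].isin(mat_ids)]
        ratio = sub["mat"].sum() / (sub["mat"] + sub["pat"]).sum()
        assert ratio == pytest.approx(0.9, abs=0.02)


class TestReads:
    def test_snp_rate_zero_leaves_reads_uninformative(self):
        cfg = SimConfig(seed=2, n_chrom=1, chrom_length=2_000_000, n_peaks=60,
                        snp_rate=0.0, n_background_ltrs=10)
        ref, truth = simdata.simulate_reference(cfg)
        # forced LTR SNPs aside, the genome-wide tables are empty
        reads, _origins = simdata.simulate_genomic_reads(
            ref, cfg, "B6/CAST", 200,
            region=simdata.GenomicInterval("chr1", 1_500_000, 1_900_000))
        assert all(len(r.snp_obs) == 0 for r in reads)

    def test_chimera_truth_has_junction_read_to_exon2(self, small_study):
        data, truth = small_study
        genes = {g.id: g for g in data.genes}
        reads = data.rna_reads["B6/CAST"]
        chimeras = truth[truth["transcript_type"] == "chimera"]
        assert not chimeras.empty
        for row in chimeras.itertuples():
            gene = genes[row.chimera_partner_gene]
            exon2 = gene.exons_in_transcription_order()[1]
            target = exon2.start if gene.strand == "+" else exon2.end
            assert any(target in jx for read in reads for jx in read.junctions)

    def test_decoy_pass_through_has_incoming_junction(self, small_study):
        data, truth = small_study
        repeats = {r.repeat_name: r for r in data.repeats}
        reads = data.rna_reads["B6/CAST"]
        decoys = truth[truth["decoy_type"] == "incoming_junction"]
        assert not decoys.empty
        for row in decoys.itertuples():
            iv = repeats[row.ltr_id].interval
            found = False
            for read in reads:
                for left, right in read.junctions:
                    acceptor = left if iv.strand == "-" else right
                    if iv.start <= acceptor < iv.end:
                        found = True
            assert found

    def test_methylation_program_levels(self, small_config, small_study):
        data, _truth = small_study
        sites = data.methyl_sites["B6/CAST"]
        by = {}
        for s in sites:
            by.setdefault((s.stage, s.allele), [0, 0])
            by[(s.stage, s.allele)][0] += s.meth_count
            by[(s.stage, s.allele)][1] += s.meth_count + s.unmeth_count
        # ExE is a mix of non-canonical (mat 0.8) and canonical regions
        gv_m = by[("GV", "maternal")]
        assert 0 < gv_m[0] / gv_m[1] < 0.7
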