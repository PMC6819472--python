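"""Counting rules, informativeness filter, normalisations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintseq import quantify
from imprintseq.core_io import Gene, GenomicInterval, Peak, ReadRecord
from imprintseq.quantify import (
    CountRegion,
    count_over_regions,
    enrichment_normalize,
    filter_informative,
    merge_peak_sets,
    running_windows,
    size_factor_normalize,
)


def _peak(pid, start, end, tissue="ExE"):
    return Peak(pid, GenomicInterval("chr1", start, end), tissue=tissue)


class TestMergePeakSets:
    def test_overlapping_peaks_merge_to_union(self):
        merged = merge_peak_sets([_peak("a", 100, 200)], [_peak("b", 150, 250)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 250)

    def test_disjoint_peaks_pass_through(self):
        merged = merge_peak_sets([_peak("a", 100, 200)], [_peak("b", 300, 400)])
        assert len(merged) == 2

    def test_identical_sets_idempotent(self):
        peaks = [_peak("a", 100, 200), _peak("b", 500, 600)]
        assert len(merge_peak_sets(peaks, peaks)) == len(peaks)

    def test_mixed_tissues_rejected(self):
        with pytest.raises(ValueError):
            merge_peak_sets([_peak("a", 0, 10, "ExE")],
                            [_peak("b", 0, 10, "epiblast")])


class TestCounting:
    def test_allelic_counts_per_peak(self):
        region = CountRegion("pk", GenomicInterval("chr1", 100, 200))
        mk = lambda i, s: ReadRecord(f"m{i}", "chr1", s, s + 50, "+")
        part = {"maternal": [mk(i, 110) for i in range(5)],
                "paternal": [mk(i, 120) for i in range(3)],
                "unassigned": []}
        df = count_over_regions(part, [region])
        assert df.loc[0, "mat"] == 5 and df.loc[0, "pat"] == 3

    def test_midpoint_rule_at_region_border(self):
        region = CountRegion("pk", GenomicInterval("chr1", 100, 200))
        inside = ReadRecord("a", "chr1", 90, 120, "+")   # midpoint 105
        outside = ReadRecord("b", "chr1", 60, 110, "+")  # midpoint 85
        df = count_over_regions({"maternal": [inside, outside]}, [region])
        assert df.loc[0, "mat"] == 1

    def test_intronic_rna_read_not_counted(self):
        gene = Gene("g", "G", GenomicInterval("chr1", 100, 1100, "+"), "+", 100,
                    (GenomicInterval("chr1", 100, 200, "+"),
                     GenomicInterval("chr1", 900, 1100, "+")))
        region = quantify.regions_from_genes([gene])[0]
        exonic = ReadRecord("a", "chr1", 120, 180, "+")
        intronic = ReadRecord("b", "chr1", 400, 500, "+")
        df = count_over_regions({"maternal": [exonic, intronic]}, [region])
        assert df.loc[0, "mat"] == 1

    def test_ltr_counting_is_strand_aware(self):
        region = CountRegion("l", GenomicInterval("chr1", 100, 500, "+"), "ltr")
        fwd = ReadRecord("a", "chr1", 200, 280, "+")
        rev = ReadRecord("b", "chr1", 200, 280, "-")
        df = count_over_regions({"maternal": [fwd, rev]}, [region])
        assert df.loc[0, "mat"] == 1


def _counts(rows):
    return pd.DataFrame([{"region_id": r, "sample_id": s, "replicate": rep,
                          "mat": m, "pat": p, "unassigned": u}
                         for r, s, rep, m, p, u in rows])


class TestFilterInformative:
    def test_boundary_cases_chip(self):
        df = _counts([("hit", "a", 1, 9, 10, 0), ("hit", "a", 2, 10, 10, 0),
                      ("miss", "a", 1, 9, 10, 0), ("miss", "a", 2, 10, 9, 0)])
        assert filter_informative(df, "chip") == ["hit"]

    def test_boundary_cases_rna(self):
        df = _counts([("g1", "a", 1, 5, 0, 0), ("g1", "a", 2, 0, 0, 0),
                      ("g2", "a", 1, 2, 2, 9)])  # unassigned never counts
        assert filter_informative(df, "rna") == ["g1"]

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError):
            filter_informative(_counts([("r", "a", 1, 5, 5, 0)]), "atac")

    @given(st.integers(1, 30))
    @settings(max_examples=20, derandomize=True)
    def test_monotone_in_threshold(self, thr):
        df = _counts([(f"r{i}", "a", 1, i, i, 0) for i in range(20)])
        hi = set(filter_informative(df, "chip", threshold=thr))
        lo = set(filter_informative(df, "chip", threshold=max(1, thr - 1)))
        assert hi <= lo


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]},
                         index=["r1", "r2", "r3"])
        _scaled, factors = size_factor_normalize(m)
        assert np.allclose(factors, 1.0)

    def test_doubled_sample_median_of_ratios(self):
        m = pd.DataFrame({"a": [10, 20, 40], "b": [20, 40, 80]},
                         index=["r1", "r2", "r3"])
        _scaled, factors = size_factor_normalize(m)
        assert factors["a"] == pytest.approx(1 / np.sqrt(2))
        assert factors["b"] == pytest.approx(np.sqrt(2))

    def test_sex_chromosome_regions_excluded_from_estimation(self):
        base = pd.DataFrame({"a": [10, 20, 40], "b": [20, 40, 80]},
                            index=["r1", "r2", "r3"])
        with_x = pd.concat([base, pd.DataFrame({"a": [100], "b": [10_000]},
                                               index=["rx"])])
        chrom = {"r1": "chr1", "r2": "chr1", "r3": "chr2", "rx": "chrX"}
        _s, factors = size_factor_normalize(with_x, chrom_by_region=chrom)
        _s2, factors_base = size_factor_normalize(
            base, chrom_by_region={k: chrom[k] for k in base.index})
        assert np.allclose(factors, factors_base)


class TestRunningWindows:
    def test_window_count_on_10kb_chromosome(self):
        windows, _ = running_windows([], {"chr1": 10_000}, library_size=1)
        assert len(windows) == 91  # (10000 - 1000) / 100 + 1

    def test_rpkm_unit_definition(self):
        read = ReadRecord("r", "chr1", 400, 600, "+")  # midpoint 500
        windows, rpkm = running_windows([read], {"chr1": 10_000},
                                        library_size=10**6)
        hit = [v for w, v in zip(windows, rpkm)
               if w.start <= 500 < w.end]
        assert hit and all(v == pytest.approx(1.0) for v in hit)

    def test_zero_reads_zero_track(self):
        _w, rpkm = running_windows([], {"chr1": 5_000}, library_size=100)
        assert np.all(rpkm == 0)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            running_windows([], {"chr1": 5_000})

    def test_non_overlapping_windows_conserve_reads(self):
        """At step = width every midpoint-assignable read counts once."""
        rng = np.random.default_rng(6)
        reads = [ReadRecord(f"r{i}", "chr1", int(s), int(s) + 100, "+")
                 for i, s in enumerate(rng.integers(0, 9_800, size=500))]
        windows, rpkm = running_windows(reads, {"chr1": 10_000},
                                        width=1000, step=1000,
                                        library_size=10**6)
        counts = rpkm * (10**6 / 1e6) * (1000 / 1000)
        covered_lo, covered_hi = windows[0].start, windows[-1].end
        assignable = sum(covered_lo <= r.midpoint() < covered_hi for r in reads)
        assert counts.sum() == pytest.approx(assignable)


class TestEnrichmentNormalize:
    def test_percentile_anchors(self):
        values = np.arange(0, 102, dtype=float)  # non-zero part: 1..101
        out = enrichment_normalize(values)
        p40, p99 = np.percentile(values[values != 0], [40, 99])
        assert out[values == p40][0] == pytest.approx(0.0)
        assert out[values == p99][0] == pytest.approx(1.0)

    def test_affine_preserves_order_and_correlation(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 5.0, size=500)
        out = enrichment_normalize(values)
        assert np.all(np.diff(out[np.argsort(values)]) >= 0)
        assert np.corrcoef(values, out)[0, 1] == pytest.approx(1.0)

    def test_degenerate_track_rejected(self):
        with pytest.raises(ValueError):
            enrichment_normalize(np.array([0.0, 5.0, 5.0, 5.0]))
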