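"""Replicate peak merging, per-peak 5mC, metagene binning, stage summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epicrosstalk.cooccurrence import (bin_edges, global_methylation,
                                       merge_replicate_peaks,
                                       metagene_profile, peak_methylation,
                                       stage_correlation)
from epicrosstalk.errors import DataError
from epicrosstalk.io import MethylationTable, PeakSet
from epicrosstalk.simulate import SimulationConfig, simulate_methylome_and_peaks

from conftest import make_methylation


def peaks_from(intervals, chrom="chr1", strand="+"):
    rows = []
    for i, iv in enumerate(intervals):
        s, e = iv[:2]
        rows.append({"chrom": chrom if len(iv) < 3 else iv[2],
                     "start": s, "end": e, "strand": strand,
                     "gene_id": None, "peak_id": f"p{i + 1}"})
    return PeakSet(pd.DataFrame(rows))


class TestMergeReplicatePeaks:
    def test_overlapping_pair_unioned(self):
        merged = merge_replicate_peaks(peaks_from([(100, 200)]),
                                       peaks_from([(150, 250)]))
        assert len(merged) == 1
        row = merged.peaks.iloc[0]
        assert (row["start"], row["end"]) == (100, 250)

    def test_single_replicate_peak_dropped(self):
        merged = merge_replicate_peaks(peaks_from([(100, 200), (300, 400)]),
                                       peaks_from([(150, 250)]))
        assert merged.peaks["start"].tolist() == [100]

    def test_idempotent_on_identical_sets(self):
        reps = peaks_from([(10, 50), (100, 160)])
        merged = merge_replicate_peaks(reps, reps)
        assert merged.peaks[["start", "end"]].values.tolist() == \
            [[10, 50], [100, 160]]

    def test_touching_intervals_do_not_overlap(self):
        # [100,200) and [200,300) share no base under half-open coordinates
        merged = merge_replicate_peaks(peaks_from([(100, 200)]),
                                       peaks_from([(200, 300)]))
        assert len(merged) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)),
                    min_size=1, max_size=6),
           st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)),
                    min_size=1, max_size=6))
    def test_against_per_base_oracle(self, iv1, iv2):
        """Merged peaks = connected base runs covered by surviving peaks."""
        rep1 = peaks_from([(s, s + l) for s, l in iv1])
        rep2 = peaks_from([(s, s + l) for s, l in iv2])
        bases1 = [set(range(s, s + l)) for s, l in iv1]
        bases2 = [set(range(s, s + l)) for s, l in iv2]
        all2 = set().union(*bases2)
        all1 = set().union(*bases1)
        surviving = [b for b in bases1 if b & all2] + \
                    [b for b in bases2 if b & all1]
        covered = set().union(*surviving) if surviving else set()
        expected_runs = []
        for base in sorted(covered):
            if expected_runs and base == expected_runs[-1][1]:
                expected_runs[-1] = (expected_runs[-1][0], base + 1)
            else:
                expected_runs.append((base, base + 1))
        merged = merge_replicate_peaks(rep1, rep2)
        got = [tuple(r) for r in merged.peaks[["start", "end"]].values]
        assert got == expected_runs


class TestPeakMethylation:
    def test_unweighted_mean(self):
        peaks = peaks_from([(100, 200)])
        meth = make_methylation("w1", "chr1", [110, 150, 190],
                                [0.2, 0.4, 0.6])
        out = peak_methylation(peaks, meth)
        assert out.iloc[0]["level"] == pytest.approx(0.4)
        assert out.iloc[0]["n_cpgs"] == 3

    def test_no_cpgs_undefined(self):
        peaks = peaks_from([(100, 200)])
        meth = make_methylation("w1", "chr1", [500], [0.2])
        out = peak_methylation(peaks, meth)
        assert np.isnan(out.iloc[0]["level"])

    def test_coverage_weighting(self):
        peaks = peaks_from([(0, 100)])
        meth = MethylationTable(pd.DataFrame({
            "sample_id": ["w1", "w1"], "chrom": ["chr1", "chr1"],
            "pos": [10, 20], "meth_level": [1.0, 0.0], "coverage": [9, 1]}))
        unweighted = peak_methylation(peaks, meth).iloc[0]["level"]
        weighted = peak_methylation(peaks, meth,
                                    weighting="coverage").iloc[0]["level"]
        assert unweighted == pytest.approx(0.5)
        assert weighted == pytest.approx(0.9)

    def test_boundary_positions_half_open(self):
        peaks = peaks_from([(100, 200)])
        meth = make_methylation("w1", "chr1", [99, 100, 199, 200],
                                [1.0, 0.2, 0.4, 1.0])
        out = peak_methylation(peaks, meth)
        assert out.iloc[0]["n_cpgs"] == 2
        assert out.iloc[0]["level"] == pytest.approx(0.3)


class TestBinEdges:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(start=st.integers(0, 10_000), length=st.integers(20, 5000),
           n_bins=st.sampled_from([10, 20]))
    def test_partition_property(self, start, length, n_bins):
        """Bins partition the region exactly; per-base assignment agrees."""
        edges = bin_edges(start, start + length, n_bins)
        widths = np.diff(edges)
        assert widths.sum() == length
        assert (widths > 0).all()
        assert edges[0] == start and edges[-1] == start + length
        width = length // n_bins
        for pos in range(start, start + length):
            idx = int(np.searchsorted(edges, pos, side="right") - 1)
            assert idx == min((pos - start) // width, n_bins - 1)

    def test_too_short_region_raises(self):
        with pytest.raises(DataError):
            bin_edges(0, 5, 10)


class TestMetageneProfile:
    def test_default_bin_geometry(self):
        """A 1000 bp peak yields 100 bp body bins and 250 bp flank bins."""
        peaks = peaks_from([(5000, 6000)])
        meth = make_methylation("w1", "chr1", range(0, 11_000, 10),
                                [0.5] * 1100)
        prof = metagene_profile(peaks, meth, min_cpgs_per_bin=1)
        assert len(prof.table) == 50
        assert prof.table["region"].value_counts().to_dict() == {
            "upstream": 20, "peak": 10, "downstream": 20}
        # 250 bp flank bins hold 25 CpGs at 10 bp spacing, body bins 10
        assert set(prof.table.loc[prof.table.region == "upstream",
                                  "n_cpgs"]) == {25}
        assert set(prof.table.loc[prof.table.region == "peak",
                                  "n_cpgs"]) == {10}

    def test_uniform_methylome_flat_profile(self):
        peaks = peaks_from([(5000, 6000)])
        meth = make_methylation("w1", "chr1", range(0, 11_000, 25),
                                [0.8] * 440)
        prof = metagene_profile(peaks, meth, min_cpgs_per_bin=1)
        defined = prof.table["mean_meth"].dropna()
        np.testing.assert_allclose(defined, 0.8, atol=1e-12)

    def test_min_cpg_boundary_keeps_20_drops_19(self):
        peaks = peaks_from([(5000, 6000)])
        # 20 CpGs in upstream bin 0, 19 in upstream bin 1, none elsewhere
        bin0 = np.arange(20)  # positions 0..19 inside [0, 250)
        bin1 = 250 + np.arange(19)
        meth = make_methylation("w1", "chr1",
                                np.concatenate([bin0, bin1]),
                                [0.5] * 39)
        prof = metagene_profile(peaks, meth, min_cpgs_per_bin=20)
        assert prof.table.iloc[0]["n_instances"] == 1
        assert prof.table.iloc[0]["mean_meth"] == pytest.approx(0.5)
        assert prof.table.iloc[1]["n_instances"] == 0
        assert np.isnan(prof.table.iloc[1]["mean_meth"])

    def test_minus_strand_mirrors_plus_profile(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(11_000, size=2000, replace=False))
        levels = rng.uniform(0, 1, size=2000)
        meth = make_methylation("w1", "chr1", pos, levels)
        plus = metagene_profile(peaks_from([(5000, 6000)]), meth,
                                min_cpgs_per_bin=1)
        minus = metagene_profile(peaks_from([(5000, 6000)], strand="-"),
                                 meth, min_cpgs_per_bin=1)
        np.testing.assert_allclose(minus.table["mean_meth"],
                                   plus.table["mean_meth"][::-1], atol=1e-12)

    def test_pooled_body_mean_equals_in_peak_cpg_mean(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(11_000, size=1500, replace=False))
        levels = rng.uniform(0, 1, size=1500)
        meth = make_methylation("w1", "chr1", pos, levels)
        peaks = peaks_from([(5000, 6000)])
        prof = metagene_profile(peaks, meth, min_cpgs_per_bin=1,
                                aggregation="pooled")
        body = prof.table[prof.table.region == "peak"]
        pooled = (body["mean_meth"] * body["n_cpgs"]).sum() / body["n_cpgs"].sum()
        inside = (pos >= 5000) & (pos < 6000)
        assert pooled == pytest.approx(levels[inside].mean(), abs=1e-12)

    def test_short_peak_skipped(self):
        peaks = peaks_from([(5000, 5005)])
        meth = make_methylation("w1", "chr1", [5001], [0.5])
        prof = metagene_profile(peaks, meth, min_cpgs_per_bin=1)
        assert prof.table["n_instances"].sum() == 0

    def test_planted_elevation_recovered(self):
        cfg = SimulationConfig(seed=12, n_peaks=25, flank_meth_mean=0.5,
                               peak_meth_delta=0.4,
                               peak_len_range=(1000, 3000))
        meth, reps, truth = simulate_methylome_and_peaks(cfg)
        one = MethylationTable(meth.for_sample("wgbs_s30_r1"))
        prof = metagene_profile(truth.consensus_peaks, one)
        body = prof.region_means("peak")
        flank = np.concatenate([prof.region_means("upstream"),
                                prof.region_means("downstream")])
        assert np.nanmean(body) == pytest.approx(0.9, abs=0.05)
        assert np.nanmean(flank) == pytest.approx(0.5, abs=0.05)

    def test_profile_invariant_to_peak_order(self):
        rng = np.random.default_rng(10)
        pos = np.sort(rng.choice(40_000, size=4000, replace=False))
        meth = make_methylation("w1", "chr1", pos,
                                rng.uniform(0, 1, size=4000))
        iv = [(12_000, 13_000), (26_000, 27_500)]
        p1 = metagene_profile(peaks_from(iv), meth, min_cpgs_per_bin=1)
        p2 = metagene_profile(peaks_from(iv[::-1]), meth, min_cpgs_per_bin=1)
        np.testing.assert_allclose(p1.table["mean_meth"],
                                   p2.table["mean_meth"], atol=1e-12)


class TestStageSummaries:
    def test_global_methylation_simple(self):
        assert global_methylation(
            make_methylation("w1", "chr1", [1, 2], [0.0, 1.0])) == 0.5
        assert global_methylation(
            make_methylation("w1", "chr1", [5], [0.73])) == 0.73

    def test_replicates_averaged_as_means_of_means(self):
        rep1 = make_methylation("w1", "chr1", [1, 2, 3, 4], [0.1] * 4)
        rep2 = make_methylation("w2", "chr1", [1, 2], [0.5, 0.7])
        both = MethylationTable(pd.concat([rep1.records, rep2.records],
                                          ignore_index=True))
        # mean of per-replicate means, not of pooled records
        assert global_methylation(both) == pytest.approx((0.1 + 0.6) / 2)

    def test_stage_correlation_affine(self):
        x = np.array([1.0, 2, 3, 4])
        assert stage_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert stage_correlation(x, -x).r == pytest.approx(-1.0)

    def test_stage_correlation_matches_formula(self):
        x = np.array([0.71, 0.68, 0.66, 0.65])
        y = np.array([8969.0, 10_542, 11_830, 12_221])
        res = stage_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert res.r == pytest.approx(r_expected, abs=1e-12)
        assert 0 < res.p <= 1
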