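import math

import numpy as np
import pytest

from methsite.intervals import ChromSizes, GenomicInterval
from methsite.tracks import (
    CoverageTrack,
    average_profile,
    cpg_density_track,
    cpg_positions,
    mean_signal,
    read_bedgraph,
    region_matrix,
    region_means,
    rpm_normalize,
    write_bedgraph,
)

SIZES = ChromSizes({"chr1": 300, "chr2": 120})


from _oracles import oracle_mean, per_base_expand


def random_track(rng, sizes, bin_size, missing_frac=0.2):
    data = {}
    for chrom, L in sizes.items():
        n = math.ceil(L / bin_size)
        v = rng.normal(size=n)
        v[rng.random(n) < missing_frac] = np.nan
        data[chrom] = v
    return CoverageTrack(bin_size=bin_size, data=data)


class TestReadBedgraph:
    def test_whole_bin_record(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t10\t3\n")
        track = read_bedgraph(p, SIZES, bin_size=10)
        assert track.data["chr1"][0] == 3.0
        assert np.isnan(track.data["chr1"][1])

    def test_coverage_weighted_mean_of_half_bins(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t5\t2\nchr1\t5\t10\t4\n")
        track = read_bedgraph(p, SIZES, bin_size=10)
        assert track.data["chr1"][0] == pytest.approx(3.0)

    def test_record_beyond_chromosome_end_errors(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr2\t100\t200\t1\n")
        with pytest.raises(ValueError, match="chr2:100-200"):
            read_bedgraph(p, SIZES, bin_size=10)

    def test_random_records_match_per_base_oracle(self, rng, tmp_path):
        # oracle: expand every record onto a per-base array, average per bin
        bin_size = 7
        lines, arrs = [], {c: [[] for _ in range(L)] for c, L in SIZES.items()}
        for _ in range(60):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            L = SIZES[chrom]
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, min(L, s + 40) + 1))
            v = float(rng.normal())
            lines.append(f"{chrom}\t{s}\t{e}\t{v}")
            for i in range(s, e):
                arrs[chrom][i].append(v)
        p = tmp_path / "r.bedGraph"
        p.write_text("\n".join(lines) + "\n")
        track = read_bedgraph(p, SIZES, bin_size=bin_size)
        for chrom, L in SIZES.items():
            for b in range(math.ceil(L / bin_size)):
                vals = [v for i in range(b * bin_size, min(L, (b + 1) * bin_size))
                        for v in arrs[chrom][i]]
                got = track.data[chrom][b]
                if not vals:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(np.mean(vals), abs=1e-9)

    def test_bedgraph_round_trip(self, rng, tmp_path):
        track = random_track(rng, SIZES, bin_size=10)
        p = tmp_path / "rt.bedGraph"
        write_bedgraph(track, SIZES, p)
        back = read_bedgraph(p, SIZES, bin_size=10)
        for chrom in SIZES:
            np.testing.assert_allclose(
                back.data[chrom], track.data[chrom], rtol=1e-5, equal_nan=True
            )


class TestRpmNormalize:
    def test_scaling(self):
        track = CoverageTrack(10, {"chr1": np.array([10.0, 0.0, np.nan])})
        rpm = rpm_normalize(track, 1_000_000)
        assert rpm.data["chr1"][0] == 10.0
        assert rpm.data["chr1"][1] == 0.0
        assert np.isnan(rpm.data["chr1"][2])
        assert rpm.units == "rpm"

    def test_sum_scales_exactly(self, rng):
        track = random_track(rng, SIZES, 10)
        lib = 2.5e5
        rpm = rpm_normalize(track, lib)
        for chrom in SIZES:
            assert np.nansum(rpm.data[chrom]) == pytest.approx(
                np.nansum(track.data[chrom]) * 1e6 / lib
            )

    def test_linearity(self, rng):
        a = random_track(rng, SIZES, 10, missing_frac=0)
        b = random_track(rng, SIZES, 10, missing_frac=0)
        lib = 3e5
        ab = CoverageTrack(10, {c: a.data[c] + b.data[c] for c in SIZES})
        for chrom in SIZES:
            np.testing.assert_allclose(
                rpm_normalize(ab, lib).data[chrom],
                rpm_normalize(a, lib).data[chrom] + rpm_normalize(b, lib).data[chrom],
            )

    def test_nonpositive_library_rejected(self):
        track = CoverageTrack(10, {"chr1": np.zeros(3)})
        with pytest.raises(ValueError):
            rpm_normalize(track, 0)


class TestMeanSignal:
    def test_constant_track(self):
        track = CoverageTrack(10, {"chr1": np.full(30, 2.5)})
        assert mean_signal(track, GenomicInterval("chr1", 13, 200)) == pytest.approx(2.5)

    def test_two_equal_halves(self):
        track = CoverageTrack(10, {"chr1": np.array([1.0, 3.0] + [0.0] * 28)})
        assert mean_signal(track, GenomicInterval("chr1", 0, 20)) == pytest.approx(2.0)

    def test_all_missing_returns_nan(self):
        track = CoverageTrack(10, {"chr1": np.full(30, np.nan)})
        assert np.isnan(mean_signal(track, GenomicInterval("chr1", 0, 20)))

    def test_unknown_chromosome(self):
        track = CoverageTrack(10, {"chr1": np.zeros(30)})
        with pytest.raises(KeyError):
            mean_signal(track, GenomicInterval("chrX", 0, 5))

    def test_whole_chromosome_equals_mean_of_finite_bins(self, rng):
        track = random_track(rng, ChromSizes({"chr1": 300}), 10)
        got = mean_signal(track, GenomicInterval("chr1", 0, 300))
        assert got == pytest.approx(np.nanmean(track.data["chr1"]))

    def test_matches_per_base_oracle_on_random_regions(self, rng):
        for _ in range(300):
            bin_size = int(rng.integers(1, 15))
            track = random_track(rng, SIZES, bin_size)
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            L = SIZES[chrom]
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, L + 1))
            region = GenomicInterval(chrom, s, e)
            got = mean_signal(track, region)
            want = oracle_mean(track, region, L)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)


class TestRegionMatrix:
    def test_constant_track_fills_constant(self):
        track = CoverageTrack(10, {"chr1": np.full(30, 4.0)})
        regions = [GenomicInterval("chr1", 100, 140), GenomicInterval("chr1", 150, 200)]
        m = region_matrix(track, regions, upstream=50, downstream=50)
        assert m.values.shape == (2, 10)
        assert np.all(m.values == 4.0)

    def test_region_at_chromosome_start_has_missing_upstream(self):
        track = CoverageTrack(10, {"chr1": np.zeros(30)})
        m = region_matrix(track, [GenomicInterval("chr1", 0, 20)], upstream=50, downstream=50)
        # anchor = 10; leading columns fall before position 0
        assert np.isnan(m.values[0, :4]).all()
        assert np.isfinite(m.values[0, 5:]).all()

    def test_delta_at_center_is_argmax_of_center_column(self, rng):
        bin_size = 10
        track = CoverageTrack(bin_size, {"chr1": np.zeros(100)})
        regions = []
        for s in (200, 400, 600):
            region = GenomicInterval("chr1", s, s + 60)
            track.data["chr1"][region.center() // bin_size] = 100.0
            regions.append(region)
        m = region_matrix(track, regions, upstream=100, downstream=100)
        center_col = 100 // bin_size  # first downstream column starts at the anchor
        assert (m.values.argmax(axis=1) == center_col).all()

    def test_scaled_body_mode_column_count_and_values(self):
        track = CoverageTrack(10, {"chr1": np.arange(30, dtype=float)})
        region = GenomicInterval("chr1", 100, 200)
        m = region_matrix(track, [region], upstream=20, downstream=20, mode="scaled-body", body_bins=5)
        assert m.values.shape == (1, 2 + 5 + 2)
        # body column k covers 20 bp starting at 100 + 20k; bins are 10 bp wide
        expected_body = [(10.0 + 2 * k) + 0.5 for k in range(5)]
        np.testing.assert_allclose(m.values[0, 2:7], expected_body)

    def test_empty_region_collection_errors(self):
        track = CoverageTrack(10, {"chr1": np.zeros(30)})
        with pytest.raises(ValueError):
            region_matrix(track, [], upstream=10, downstream=10)

    def test_extent_must_be_bin_multiple(self):
        track = CoverageTrack(10, {"chr1": np.zeros(30)})
        with pytest.raises(ValueError):
            region_matrix(track, [GenomicInterval("chr1", 100, 120)], upstream=15, downstream=10)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(100):
            bin_size = int(rng.integers(2, 12))
            track = random_track(rng, SIZES, bin_size)
            chrom = "chr1"
            L = SIZES[chrom]
            s = int(rng.integers(20, L - 40))
            e = int(rng.integers(s + 1, min(L, s + 30)))
            up = bin_size * int(rng.integers(1, 4))
            down = bin_size * int(rng.integers(1, 4))
            region = GenomicInterval(chrom, s, e)
            m = region_matrix(track, [region], upstream=up, downstream=down)
            base = per_base_expand(track, chrom, math.ceil(L / bin_size) * bin_size)
            anchor = region.center()
            for j in range(m.values.shape[1]):
                w0 = anchor - up + j * bin_size
                w1 = w0 + bin_size
                if w0 < 0 or w1 > len(base):
                    assert np.isnan(m.values[0, j])
                    continue
                window = base[w0:w1]
                finite = window[np.isfinite(window)]
                if finite.size == 0:
                    assert np.isnan(m.values[0, j])
                else:
                    assert m.values[0, j] == pytest.approx(finite.mean(), abs=1e-9)


class TestAverageProfile:
    def test_single_row_is_identity(self):
        track = CoverageTrack(10, {"chr1": np.arange(30, dtype=float)})
        m = region_matrix(track, [GenomicInterval("chr1", 100, 120)], upstream=20, downstream=20)
        np.testing.assert_allclose(average_profile(m), m.values[0])

    def test_opposite_rows_cancel(self):
        from methsite.tracks import RegionMatrix

        r = np.array([1.0, -2.0, 3.0])
        m = RegionMatrix(np.vstack([r, -r]), bin_size=1, upstream=1, downstream=2)
        np.testing.assert_allclose(average_profile(m), np.zeros(3))

    def test_matches_naive_loop_with_missing(self, rng):
        from methsite.tracks import RegionMatrix

        vals = rng.normal(size=(20, 8))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        vals[:, 3] = np.nan  # one all-missing column
        m = RegionMatrix(vals, bin_size=1, upstream=4, downstream=4)
        prof = average_profile(m)
        for j in range(8):
            col = [v for v in vals[:, j] if np.isfinite(v)]
            if not col:
                assert np.isnan(prof[j])
            else:
                assert prof[j] == pytest.approx(np.mean(col))

    def test_n_identical_regions_equal_single_region_profile(self):
        track = CoverageTrack(10, {"chr1": np.arange(30, dtype=float)})
        region = GenomicInterval("chr1", 100, 150)
        single = average_profile(region_matrix(track, [region], 20, 20))
        many = average_profile(region_matrix(track, [region] * 7, 20, 20))
        np.testing.assert_allclose(single, many)


class TestCpgDensity:
    def test_hand_counts(self):
        sizes = ChromSizes({"c": 6})
        assert cpg_density_track({"c": "CGCGCG"}, sizes, 6).data["c"][0] == 3
        assert cpg_density_track({"c": "ATATAT"}, sizes, 6).data["c"][0] == 0

    def test_case_insensitive_and_n_never_matches(self):
        sizes = ChromSizes({"c": 6})
        assert cpg_density_track({"c": "cgCgNG"}, sizes, 6).data["c"][0] == 2

    def test_straddling_cg_counted_once_in_first_bin(self):
        sizes = ChromSizes({"c": 8})
        track = cpg_density_track({"c": "AAACGAAA"}, sizes, 4)
        assert track.data["c"].tolist() == [1.0, 0.0]
        track = cpg_density_track({"c": "AAACGAAA"[:4] + "GAAA"}, sizes, 4)
        # CG straddles the bin boundary at position 3
        assert track.data["c"].sum() == 1.0

    def test_total_count_equals_reverse_complement_count(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=200))
            rc = seq.translate(comp)[::-1]
            assert len(cpg_positions(seq)) == len(cpg_positions(rc))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            cpg_density_track({"c": "ACGT"}, ChromSizes({"c": 5}), 2)


def test_region_means_vector_matches_scalar(rng):
    track = random_track(rng, SIZES, 10)
    regions = [GenomicInterval("chr1", 5, 60), GenomicInterval("chr2", 0, 120)]
    got = region_means(track, regions)
    np.testing.assert_allclose(got, [mean_signal(track, r) for r in regions], equal_nan=True)
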