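"""Coverage binning, peak calling, rearrangement classification, ideotypes."""

import numpy as np
import pytest

from oligopaint.core import DesignParameters, Genome, GenomicInterval
from oligopaint.hybridization import (
    CallType,
    HybridizationPeak,
    compare_genomes,
    ideotype_table,
    simulate_hybridization,
)
from oligopaint.mapping import MapHit, Orientation


def make_hits(chrom, starts, region="r1", fluor="Atto488", origin0=0):
    return [
        MapHit(
            oligo_id=f"o{i}",
            location=GenomicInterval(chrom, s, s + 47),
            strand="+", mismatches=0, region_id=region, fluorochrome=fluor,
            origin_start=origin0 + i * 50,
        )
        for i, s in enumerate(starts)
    ]


@pytest.fixture
def genome_2mb():
    # hybridization only needs chromosome lengths; content is irrelevant
    return Genome("g", {"c1": "A" * 2_000_000, "c2": "A" * 1_000_000})


class TestSimulateHybridization:
    def test_empty_hit_list_no_peaks(self, genome_2mb, params):
        profiles, peaks = simulate_hybridization([], genome_2mb, params)
        assert peaks == []
        assert all(p.counts.sum() == 0 for p in profiles)

    def test_uniform_hits_in_window_give_single_peak(self, genome_2mb, params):
        rng = np.random.default_rng(5)
        starts = sorted(rng.integers(500_000, 1_500_000 - 47, size=200))
        hits = make_hits("c1", starts)
        profiles, peaks = simulate_hybridization(hits, genome_2mb, params)
        assert len(peaks) == 1
        peak = peaks[0]
        assert peak.intensity == 200
        assert peak.span.start >= 400_000 and peak.span.end <= 1_600_000
        assert peak.source_region == "r1" and peak.fluorochrome == "Atto488"
        assert peak.orientation is Orientation.FORWARD

    def test_bin_counts_conserve_hits(self, genome_2mb, params):
        rng = np.random.default_rng(6)
        hits = make_hits("c1", rng.integers(0, 1_999_953, size=137)) + make_hits(
            "c2", rng.integers(0, 999_953, size=61), region="r2"
        )
        profiles, _ = simulate_hybridization(hits, genome_2mb, params)
        by_chrom = {p.chrom: p for p in profiles}
        assert by_chrom["c1"].counts.sum() == 137
        assert by_chrom["c2"].counts.sum() == 61

    def test_one_gap_bin_does_not_split_a_peak(self, genome_2mb, params):
        # bins 0 and 2 above threshold, bin 1 silent -> one merged peak
        hits = make_hits("c1", [10_000 + i * 100 for i in range(10)])
        hits += make_hits("c1", [210_000 + i * 100 for i in range(10)])
        _, peaks = simulate_hybridization(hits, genome_2mb, params)
        assert len(peaks) == 1
        assert peaks[0].intensity == 20

    def test_two_gap_bins_split_peaks(self, genome_2mb, params):
        hits = make_hits("c1", [10_000 + i * 100 for i in range(10)])
        hits += make_hits("c1", [310_000 + i * 100 for i in range(10)])
        _, peaks = simulate_hybridization(hits, genome_2mb, params)
        assert len(peaks) == 2

    def test_sub_threshold_bins_yield_no_peak(self, genome_2mb, params):
        hits = make_hits("c1", [10_000, 20_000, 30_000, 40_000])  # 4 < 5
        _, peaks = simulate_hybridization(hits, genome_2mb, params)
        assert peaks == []

    def test_peak_intensities_sum_to_clustered_hits(self, genome_2mb, params):
        rng = np.random.default_rng(7)
        hits = make_hits("c1", sorted(rng.integers(100_000, 180_000, size=50)))
        hits += make_hits("c1", sorted(rng.integers(900_000, 950_000, size=30)),
                          region="r2")
        hits += make_hits("c2", [500_000], region="r3")  # lone hit: unclustered
        _, peaks = simulate_hybridization(hits, genome_2mb, params)
        assert sum(p.intensity for p in peaks) == 80

    def test_position_is_hit_weighted_mean(self, genome_2mb, params):
        hits = make_hits("c1", [100_000] * 6 + [120_000] * 2)
        _, [peak] = simulate_hybridization(hits, genome_2mb, params)
        expected = (6 * 100_023.5 + 2 * 120_023.5) / 8
        assert peak.position == pytest.approx(expected)


def _peak(chrom, start, end, region, intensity=100, fluor="Atto488",
          orientation=Orientation.FORWARD, genome_id="g"):
    return HybridizationPeak(
        peak_id=f"{genome_id}:{chrom}:{start}", genome_id=genome_id, chrom=chrom,
        span=GenomicInterval(chrom, start, end), intensity=intensity,
        width=end - start, position=(start + end) / 2, source_region=region,
        fluorochrome=fluor, orientation=orientation,
    )


class TestCompareGenomes:
    def _source(self):
        return [
            _peak("c1", 100_000, 200_000, "r1a"),
            _peak("c1", 700_000, 800_000, "r1b"),
            _peak("c2", 100_000, 200_000, "r2"),
        ]

    def test_identical_peak_sets_yield_no_calls(self, params):
        src = self._source()
        assert compare_genomes(src, src, params=params) == []

    def test_moved_region_is_a_translocation(self, params):
        dst = self._source()
        dst[1] = _peak("c2", 700_000, 800_000, "r1b")  # r1b moved c1 -> c2
        calls = compare_genomes(self._source(), dst, params=params)
        assert [(c.type, c.source_regions) for c in calls] == [
            (CallType.TRANSLOCATION, ["r1b"])
        ]

    def test_missing_region_is_a_deletion(self, params):
        dst = [p for p in self._source() if p.source_region != "r2"]
        calls = compare_genomes(self._source(), dst, params=params)
        assert [(c.type, c.source_regions) for c in calls] == [
            (CallType.DELETION, ["r2"])
        ]

    def test_residual_hits_block_deletion_call(self, params):
        dst = [p for p in self._source() if p.source_region != "r2"]
        calls = compare_genomes(
            self._source(), dst,
            raw_hits_per_region={"r2": params.block_min_hits}, params=params,
        )
        assert calls == []  # weak signal, not absence

    def test_extra_peak_is_a_duplication(self, params):
        dst = self._source() + [_peak("c2", 600_000, 700_000, "r2")]
        calls = compare_genomes(self._source(), dst, params=params)
        assert [(c.type, c.source_regions) for c in calls] == [
            (CallType.DUPLICATION, ["r2"])
        ]
        assert len(calls[0].evidence) == 2

    def test_reverse_orientation_is_a_reorientation(self, params):
        dst = self._source()
        dst[2] = _peak("c2", 100_000, 200_000, "r2", orientation=Orientation.REVERSE)
        calls = compare_genomes(self._source(), dst, params=params)
        assert [(c.type, c.source_regions) for c in calls] == [
            (CallType.REORIENTATION, ["r2"])
        ]

    def test_two_source_chromosomes_on_one_destination_is_a_fusion(self, params):
        dst = [
            _peak("cX", 100_000, 200_000, "r1a"),
            _peak("cX", 700_000, 800_000, "r1b"),
            _peak("cX", 2_100_000, 2_200_000, "r2"),
        ]
        calls = compare_genomes(self._source(), dst, params=params)
        assert [c.type for c in calls] == [CallType.FUSION]
        assert calls[0].source_regions == ["c1", "c2"]


class TestIdeotype:
    def test_band_fraction_tracks_position(self, genome_2mb):
        peaks = [_peak("c1", 950_000, 1_050_000, "r1")]
        [band] = ideotype_table(peaks, genome_2mb)
        assert band.fraction == pytest.approx(0.5)
        assert band.color == "Atto488"

    def test_same_color_peaks_stay_separate_bands(self, genome_2mb):
        peaks = [
            _peak("c1", 100_000, 200_000, "r1"),
            _peak("c1", 1_500_000, 1_600_000, "r2"),
        ]
        bands = ideotype_table(peaks, genome_2mb)
        assert len(bands) == 2
        assert bands[0].fraction < bands[1].fraction

    def test_full_design_band_count_matches_planted_regions(self, demo_design):
        spec, genome, truth, _, _, result = demo_design
        bands = ideotype_table(result.peaks_source, genome)
        per_chrom = {}
        for b in bands:
            per_chrom[b.chrom] = per_chrom.get(b.chrom, 0) + 1
        planted = {}
        for t in truth.targets:
            planted[t.interval.chrom] = planted.get(t.interval.chrom, 0) + 1
        assert per_chrom == planted
        # band colors match the planted fluorochromes
        fluor_by_region = {t.region_id: t.fluorochrome for t in truth.targets}
        for b in bands:
            assert b.color == fluor_by_region[b.source_region]
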