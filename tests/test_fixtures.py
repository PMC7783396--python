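"""The synthetic genome/read generator and the derived sister genome."""

import numpy as np
import pytest

from oligopaint.core import DesignParameters, encode, revcomp
from oligopaint.fixtures import (
    FixtureSpec,
    RearrangementSpec,
    RepeatFamilySpec,
    TargetSpec,
    default_fixture_spec,
    derive_genome,
    make_genome,
    simulate_reads,
)


def small_spec(seed=1, **overrides) -> FixtureSpec:
    base = dict(
        chrom_lengths={"c1": 120_000, "c2": 80_000},
        targets=[
            TargetSpec("c1", 30_000, 10_000, "t1", "Atto488"),
            TargetSpec("c2", 40_000, 10_000, "t2", "Atto550"),
        ],
        seed=seed,
    )
    base.update(overrides)
    return FixtureSpec(**base)


class TestMakeGenome:
    def test_same_seed_identical_genomes(self):
        g1, _ = make_genome(small_spec(seed=3))
        g2, _ = make_genome(small_spec(seed=3))
        assert g1.sequences == g2.sequences
        g3, _ = make_genome(small_spec(seed=4))
        assert g3.sequences != g1.sequences

    def test_tandem_family_planted_verbatim(self):
        spec = small_spec(repeat_families=[
            RepeatFamilySpec("fam", 180, 100, "tandem", "c1", 60_000),
        ])
        genome, truth = make_genome(spec)
        [planted] = truth.repeats
        monomer = planted.monomer
        block = genome.sequences["c1"][60_000 : 60_000 + 18_000]
        assert block == monomer * 100
        assert (planted.interval.start, planted.interval.end) == (60_000, 78_000)

    def test_dispersed_family_avoids_targets(self):
        spec = small_spec(repeat_families=[
            RepeatFamilySpec("disp", 300, 30, "dispersed"),
        ])
        genome, truth = make_genome(spec)
        assert len(truth.repeats) == 30
        for r in truth.repeats:
            assert genome.fetch(r.interval) == r.monomer
            for t in truth.targets:
                assert not r.interval.overlaps(t.interval)

    def test_overlapping_targets_rejected(self):
        with pytest.raises(ValueError):
            make_genome(small_spec(targets=[
                TargetSpec("c1", 30_000, 10_000, "t1", "Atto488"),
                TargetSpec("c1", 35_000, 10_000, "t2", "Atto550"),
            ]))

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_repeat_free_megabase_has_no_frequent_32mer(self, seed):
        spec = FixtureSpec(
            chrom_lengths={"c1": 1_000_000},
            targets=[TargetSpec("c1", 0, 10_000, "t", "Atto488")],
            seed=seed,
        )
        genome, _ = make_genome(spec)
        arr = encode(genome.sequences["c1"])
        k = 32
        codes = np.zeros(arr.size - k + 1, dtype=np.uint64)
        for j in range(k):
            codes |= arr[j : j + codes.size].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
        _, counts = np.unique(codes, return_counts=True)
        assert counts.max() < 5


class TestDeriveGenome:
    def test_zero_divergence_no_events_identity(self):
        genome, truth = make_genome(small_spec())
        genome2, truth2 = derive_genome(genome, truth, 0.0, 0.0, [], seed=9)
        assert genome2.sequences == genome.sequences
        for t in truth.targets:
            assert truth2.regions[t.region_id] == [
                type(t.interval)(t.interval.chrom, t.interval.start,
                                 t.interval.end, "derived")
            ]

    def test_substitution_rate_matches_request(self):
        genome, truth = make_genome(small_spec())
        genome2, _ = derive_genome(genome, truth, 0.05, 0.0, [], seed=10)
        a = encode(genome.sequences["c1"])
        b = encode(genome2.sequences["c1"])
        frac = (a != b).mean()
        assert abs(frac - 0.05) <= 0.01

    def test_translocation_moves_sequence_verbatim(self):
        genome, truth = make_genome(small_spec())
        events = [RearrangementSpec("translocation", "t1", "c2", 10_000)]
        genome2, truth2 = derive_genome(genome, truth, 0.0, 0.0, events, seed=11)
        original = genome.fetch(truth.targets[0].interval)
        [moved] = truth2.regions["t1"]
        assert moved.chrom == "c2" and genome2.fetch(moved) == original
        assert original not in genome2.sequences["c1"]
        # t2 sits downstream of the insertion point and must shift by +10 kb
        [t2_iv] = truth2.regions["t2"]
        assert t2_iv.start == 50_000

    def test_deletion_removes_sequence(self):
        genome, truth = make_genome(small_spec())
        genome2, truth2 = derive_genome(
            genome, truth, 0.0, 0.0, [RearrangementSpec("deletion", "t1")], seed=12
        )
        assert truth2.regions["t1"] == []
        assert len(genome2.sequences["c1"]) == 110_000
        assert genome.fetch(truth.targets[0].interval) not in genome2.sequences["c1"]

    def test_inversion_reverse_complements_in_place(self):
        genome, truth = make_genome(small_spec())
        genome2, truth2 = derive_genome(
            genome, truth, 0.0, 0.0, [RearrangementSpec("inversion", "t2")], seed=13
        )
        iv = truth.targets[1].interval
        assert genome2.fetch(iv) == revcomp(genome.fetch(iv))
        assert truth2.orientation["t2"] == "reverse"

    def test_duplication_keeps_original_and_copy(self):
        genome, truth = make_genome(small_spec())
        events = [RearrangementSpec("duplication", "t1", "c2", 70_000)]
        genome2, truth2 = derive_genome(genome, truth, 0.0, 0.0, events, seed=14)
        original = genome.fetch(truth.targets[0].interval)
        copies = truth2.regions["t1"]
        assert len(copies) == 2
        for iv in copies:
            assert genome2.fetch(iv) == original

    def test_event_on_deleted_region_conflicts(self):
        genome, truth = make_genome(small_spec())
        events = [
            RearrangementSpec("deletion", "t1"),
            RearrangementSpec("inversion", "t1"),
        ]
        with pytest.raises(ValueError):
            derive_genome(genome, truth, 0.0, 0.0, events, seed=15)

    def test_indels_shift_downstream_coordinates(self):
        genome, truth = make_genome(small_spec())
        genome2, truth2 = derive_genome(genome, truth, 0.0, 5e-4, [], seed=16)
        # coordinates track the planted sequence to within the indel sizes
        for t in truth.targets:
            [iv] = truth2.regions[t.region_id]
            window = genome2.sequences[iv.chrom][max(0, iv.start - 50) : iv.end + 50]
            probe = genome.fetch(t.interval)[:60]
            assert probe[:40] in window or probe[10:50] in window


class TestSimulateReads:
    def test_read_count_matches_coverage(self):
        genome, _ = make_genome(small_spec())  # 200 kb total
        reads = simulate_reads(genome, coverage=10, read_len=100, seed=5)
        assert len(reads) == 20_000
        assert all(len(r) == 100 for r in reads)

    def test_same_seed_same_reads(self):
        genome, _ = make_genome(small_spec())
        assert simulate_reads(genome, 1, 100, seed=6) == simulate_reads(genome, 1, 100, seed=6)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_strand_fractions_balanced(self, seed):
        spec = FixtureSpec(
            chrom_lengths={"c1": 20_000},
            targets=[TargetSpec("c1", 0, 1_000, "t", "Atto488")],
            seed=seed,
        )
        genome, _ = make_genome(spec)
        reads = simulate_reads(genome, coverage=25, read_len=50, seed=seed)
        assert len(reads) == 10_000
        fwd = sum(1 for r in reads if r in genome.sequences["c1"])
        assert abs(fwd / len(reads) - 0.5) <= 0.02

    def test_read_len_longer_than_chromosome_rejected(self):
        genome, _ = make_genome(small_spec())
        with pytest.raises(ValueError):
            simulate_reads(genome, 1, 100_000, seed=1)


def test_default_spec_elements_consistent():
    spec = default_fixture_spec(1)
    genome, truth = make_genome(spec)
    assert set(genome.sequences) == set(spec.chrom_lengths)
    assert {t.region_id for t in truth.targets} == {
        "r1a", "r1b", "r1c", "r2", "r3", "r4", "r5",
    }
    assert truth.known_repeat_sequences().keys() == {"rdna_like"}
    # planted repeats inside targets are the ones the screen must remove
    tandem = next(r for r in truth.repeats if r.name == "tandem180")
    r2 = next(t for t in truth.targets if t.region_id == "r2")
    assert r2.interval.contains(tandem.interval)
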