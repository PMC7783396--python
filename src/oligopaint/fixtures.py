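"""Deterministic synthetic genomes, reads and rearranged sister genomes.

Emulates the inputs of the probe-design workflow at desk scale: a random
background assembly at plant-like GC with planted single-copy target
regions, tandem and dispersed repeat families (including a "known" family
standing in for rDNA/organellar repeats), error-free shotgun reads, and a
diverged sister genome carrying substitutions, small indels and structural
events (translocation, inversion, deletion, duplication) at recorded
coordinates. Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Genome, GenomicInterval, decode, encode, revcomp


@dataclass(frozen=True)
class TargetSpec:
    chrom: str
    start: int
    span: int
    region_id: str
    fluorochrome: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.start + self.span)


@dataclass(frozen=True)
class RepeatFamilySpec:
    name: str
    monomer_len: int
    copies: int
    mode: str  # 'tandem' or 'dispersed'
    chrom: Optional[str] = None  # tandem placement (required for tandem)
    start: Optional[int] = None
    known: bool = False  # exported as a known-repeat sequence, not left to
    #                      the de novo k-mer screen


@dataclass(frozen=True)
class RearrangementSpec:
    type: str  # 'translocation' | 'inversion' | 'deletion' | 'duplication'
    region_id: str
    dest_chrom: Optional[str] = None
    dest_pos: Optional[int] = None


@dataclass
class FixtureSpec:
    chrom_lengths: Dict[str, int]
    targets: List[TargetSpec]
    repeat_families: List[RepeatFamilySpec] = field(default_factory=list)
    gc: float = 0.38
    divergence: float = 0.0
    indel_rate: float = 0.0
    rearrangements: List[RearrangementSpec] = field(default_factory=list)
    read_coverage: float = 4.0
    read_len: int = 150
    seed: int = 1


@dataclass
class PlantedTarget:
    region_id: str
    interval: GenomicInterval
    fluorochrome: str


@dataclass
class PlantedRepeat:
    name: str
    interval: GenomicInterval
    monomer: str
    known: bool


@dataclass
class FixtureTruth:
    targets: List[PlantedTarget]
    repeats: List[PlantedRepeat]
    seed: int

    def known_repeat_sequences(self) -> Dict[str, str]:
        """Monomers of families flagged `known`, keyed by family name."""
        return {r.name: r.monomer for r in self.repeats if r.known}

    def target_intervals(self) -> List[GenomicInterval]:
        return [t.interval for t in self.targets]


@dataclass
class DerivedTruth:
    """Post-event coordinates of each source region in the derived genome."""

    regions: Dict[str, List[GenomicInterval]]  # deleted region -> empty list
    orientation: Dict[str, str]  # 'forward' or 'reverse'
    events: List[RearrangementSpec]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def make_genome(spec: FixtureSpec, genome_id: str = "fixture") -> Tuple[Genome, FixtureTruth]:
    """Generate the source genome with planted targets and repeat families.

    Targets are intervals of the single-copy random background (random
    sequence is single-copy by construction); repeat families overwrite the
    background at recorded coordinates. A repeat placement fully inside a
    target is allowed — that is the configuration the screening stage must
    handle — but repeat/repeat and target/target overlaps are errors.
    """
    rng = np.random.default_rng(spec.seed)
    arrays = {
        chrom: _random_dna(rng, length, spec.gc)
        for chrom, length in spec.chrom_lengths.items()
    }
    targets = [
        PlantedTarget(t.region_id, t.interval, t.fluorochrome) for t in spec.targets
    ]
    for a, b in zip(sorted(spec.targets, key=lambda t: (t.chrom, t.start)),
                    sorted(spec.targets, key=lambda t: (t.chrom, t.start))[1:]):
        if a.interval.overlaps(b.interval):
            raise ValueError(f"overlapping targets {a.region_id}/{b.region_id}")
    placements: List[PlantedRepeat] = []

    def _occupied(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(p.interval) for p in placements)

    for fam in spec.repeat_families:
        monomer_codes = _random_dna(rng, fam.monomer_len, spec.gc)
        monomer = decode(monomer_codes)
        if fam.mode == "tandem":
            if fam.chrom is None or fam.start is None:
                raise ValueError(f"tandem family {fam.name} needs chrom/start")
            span = fam.monomer_len * fam.copies
            iv = GenomicInterval(fam.chrom, fam.start, fam.start + span)
            if iv.end > spec.chrom_lengths[fam.chrom]:
                raise ValueError(f"family {fam.name} exceeds chromosome")
            if _occupied(iv):
                raise ValueError(f"family {fam.name} overlaps another repeat")
            arrays[fam.chrom][iv.start : iv.end] = np.tile(monomer_codes, fam.copies)
            placements.append(PlantedRepeat(fam.name, iv, monomer, fam.known))
        elif fam.mode == "dispersed":
            chroms = list(spec.chrom_lengths)
            lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
            forbidden = [t.interval for t in spec.targets]
            placed = 0
            attempts = 0
            while placed < fam.copies:
                attempts += 1
                if attempts > fam.copies * 200:
                    raise ValueError(f"cannot place dispersed family {fam.name}")
                chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
                start = int(rng.integers(0, spec.chrom_lengths[chrom] - fam.monomer_len))
                iv = GenomicInterval(chrom, start, start + fam.monomer_len)
                if _occupied(iv) or any(iv.overlaps(t) for t in forbidden):
                    continue
                arrays[chrom][iv.start : iv.end] = monomer_codes
                placements.append(PlantedRepeat(fam.name, iv, monomer, fam.known))
                placed += 1
        else:
            raise ValueError(f"unknown repeat mode {fam.mode!r}")
    genome = Genome(
        genome_id=genome_id,
        sequences={c: decode(a) for c, a in arrays.items()},
    )
    return genome, FixtureTruth(targets=targets, repeats=placements, seed=spec.seed)


def _apply_point_changes(
    seq: str,
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> Tuple[str, List[Tuple[int, int]]]:
    """Substitutions + small indels; returns the new sequence and a list of
    (original position, signed size) indel events for coordinate shifting."""
    arr = encode(seq).copy()
    n = arr.size
    if divergence > 0:
        mask = (rng.random(n) < divergence) & (arr < 4)
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    shifts: List[Tuple[int, int]] = []
    if indel_rate > 0:
        positions = np.flatnonzero(rng.random(n) < indel_rate)
        pieces: List[np.ndarray] = []
        last = 0
        for p in positions:
            p = int(p)
            if p < last:
                continue
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:  # insertion
                pieces.append(arr[last:p])
                pieces.append(rng.integers(0, 4, size=size).astype(np.uint8))
                shifts.append((p, size))
                last = p
            else:  # deletion
                end = min(p + size, n)
                pieces.append(arr[last:p])
                shifts.append((p, -(end - p)))
                last = end
        pieces.append(arr[last:])
        arr = np.concatenate(pieces)
    return decode(arr), shifts


def _shifted(pos: int, shifts: Sequence[Tuple[int, int]], cumulative: Sequence[int]) -> int:
    i = bisect.bisect_left([s[0] for s in shifts], pos)
    return pos + (cumulative[i - 1] if i > 0 else 0)


def derive_genome(
    genome: Genome,
    truth: FixtureTruth,
    divergence: float,
    indel_rate: float,
    rearrangements: Sequence[RearrangementSpec],
    seed: int,
    genome_id: str = "derived",
) -> Tuple[Genome, DerivedTruth]:
    """Produce a diverged sister genome with the listed structural events.

    Substitutions and small (1-5 bp) indels are applied first, then events
    in list order; destination positions are interpreted in the running
    coordinates at the time each event is applied. Region coordinates are
    tracked through every step and returned as the derived truth.
    """
    rng = np.random.default_rng(seed)
    seqs: Dict[str, str] = {}
    regions: Dict[str, List[GenomicInterval]] = {}
    orientation: Dict[str, str] = {t.region_id: "forward" for t in truth.targets}
    per_chrom_shifts: Dict[str, Tuple[list, list]] = {}
    for chrom, seq in genome.sequences.items():
        new_seq, shifts = _apply_point_changes(seq, divergence, indel_rate, rng)
        seqs[chrom] = new_seq
        cum = list(np.cumsum([d for _, d in shifts])) if shifts else []
        per_chrom_shifts[chrom] = (shifts, cum)
    for t in truth.targets:
        shifts, cum = per_chrom_shifts[t.interval.chrom]
        start = _shifted(t.interval.start, shifts, cum)
        end = _shifted(t.interval.end, shifts, cum)
        regions[t.region_id] = [
            GenomicInterval(t.interval.chrom, start, max(end, start + 1),
                            genome_id=genome_id)
        ]

    def _shift_regions(chrom: str, pos: int, delta: int) -> None:
        for rid, ivs in regions.items():
            regions[rid] = [
                GenomicInterval(iv.chrom, iv.start + delta, iv.end + delta, iv.genome_id)
                if iv.chrom == chrom and iv.start >= pos
                else iv
                for iv in ivs
            ]

    def _current(rid: str) -> GenomicInterval:
        ivs = regions.get(rid, [])
        if not ivs:
            raise ValueError(f"event references missing/deleted region {rid!r}")
        return ivs[0]

    for ev in rearrangements:
        if ev.type == "deletion":
            iv = _current(ev.region_id)
            seqs[iv.chrom] = seqs[iv.chrom][: iv.start] + seqs[iv.chrom][iv.end :]
            regions[ev.region_id] = []
            _shift_regions(iv.chrom, iv.end, -len(iv))
        elif ev.type == "inversion":
            iv = _current(ev.region_id)
            s = seqs[iv.chrom]
            seqs[iv.chrom] = s[: iv.start] + revcomp(s[iv.start : iv.end]) + s[iv.end :]
            orientation[ev.region_id] = "reverse"
        elif ev.type in ("translocation", "duplication"):
            if ev.dest_chrom is None or ev.dest_pos is None:
                raise ValueError(f"{ev.type} needs dest_chrom/dest_pos")
            iv = _current(ev.region_id)
            frag = seqs[iv.chrom][iv.start : iv.end]
            for rid, ivs in regions.items():
                for other in ivs:
                    if other.chrom == ev.dest_chrom and other.start < ev.dest_pos < other.end:
                        raise ValueError(
                            f"destination of {ev.type} falls inside region {rid!r}"
                        )
            if ev.type == "translocation":
                seqs[iv.chrom] = seqs[iv.chrom][: iv.start] + seqs[iv.chrom][iv.end :]
                regions[ev.region_id] = []
                _shift_regions(iv.chrom, iv.end, -len(iv))
            d = seqs[ev.dest_chrom]
            pos = ev.dest_pos
            seqs[ev.dest_chrom] = d[:pos] + frag + d[pos:]
            _shift_regions(ev.dest_chrom, pos, len(frag))
            new_iv = GenomicInterval(ev.dest_chrom, pos, pos + len(frag),
                                     genome_id=genome_id)
            if ev.type == "translocation":
                regions[ev.region_id] = [new_iv]
            else:
                regions[ev.region_id].append(new_iv)
        else:
            raise ValueError(f"unknown rearrangement type {ev.type!r}")
    return (
        Genome(genome_id=genome_id, sequences=seqs),
        DerivedTruth(regions=regions, orientation=orientation,
                     events=list(rearrangements)),
    )


def simulate_reads(
    genome: Genome, coverage: float, read_len: int, seed: int
) -> List[str]:
    """Uniform error-free reads from both strands at the given coverage.

    The read count is ``round(coverage * genome_size / read_len)``; each read
    picks a chromosome weighted by length, a uniform start and a random
    strand. Qualities are not modeled: the k-mer stage ranks abundances.
    """
    if read_len > min(len(s) for s in genome.sequences.values()):
        raise ValueError("read_len exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    n_reads = int(round(coverage * lengths.sum() / read_len))
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=lengths / lengths.sum())
    reads: List[str] = []
    for ci in chrom_idx:
        seq = genome.sequences[chroms[ci]]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        read = seq[start : start + read_len]
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(read)
    return reads


def default_fixture_spec(seed: int = 1) -> FixtureSpec:
    """The standard desk-scale study conditions used across the test suite.

    Six chromosomes (0.9 Mb + 4 x 0.4 Mb + 0.6 Mb) carry seven single-copy
    target regions of 30-40 kb — three on the first chromosome to give it a
    multi-band barcode — one 18-kb tandem repeat array planted inside a
    target, one dispersed repeat family, and a 1-kb known-repeat insert
    inside another target. The sixth chromosome is empty, reserved as the
    destination of structural events in the derived genome.
    """
    return FixtureSpec(
        chrom_lengths={
            "c1": 900_000, "c2": 400_000, "c3": 400_000,
            "c4": 400_000, "c5": 400_000, "c6": 600_000,
        },
        targets=[
            TargetSpec("c1", 100_000, 30_000, "r1a", "Atto488"),
            TargetSpec("c1", 400_000, 30_000, "r1b", "Atto550"),
            TargetSpec("c1", 700_000, 30_000, "r1c", "Atto594"),
            TargetSpec("c2", 150_000, 40_000, "r2", "Cy5"),
            TargetSpec("c3", 150_000, 30_000, "r3", "Atto488"),
            TargetSpec("c4", 150_000, 30_000, "r4", "Atto550"),
            TargetSpec("c5", 150_000, 30_000, "r5", "Atto594"),
        ],
        repeat_families=[
            RepeatFamilySpec("tandem180", 180, 100, "tandem", "c2", 165_000),
            RepeatFamilySpec("dispersed300", 300, 60, "dispersed"),
            RepeatFamilySpec("rdna_like", 1_000, 1, "tandem", "c3", 160_000,
                             known=True),
        ],
        gc=0.38,
        divergence=0.03,
        indel_rate=2e-4,
        rearrangements=[
            RearrangementSpec("translocation", "r1b", "c6", 150_000),
            RearrangementSpec("inversion", "r5"),
            RearrangementSpec("deletion", "r3"),
            RearrangementSpec("duplication", "r4", "c6", 450_000),
        ],
        read_coverage=4.0,
        read_len=150,
        seed=seed,
    )
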