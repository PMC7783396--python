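"""Shared domain types and sequence primitives.

Coordinates are 0-based half-open everywhere inside the package; Mb values
in human-readable reports are plain ``bp / 1e6`` conversions of these.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding used by the mapping / k-mer machinery: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every character outside {A,C,G,T} to N."""
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


class OligoStatus(enum.Enum):
    CANDIDATE = "candidate"
    RETAINED = "retained"
    DISCARDED = "discarded"


class DiscardReason(enum.Enum):
    AMBIGUITY = "ambiguity"
    GC = "gc"
    KNOWN_REPEAT = "known_repeat"
    KMER_REPEAT = "kmer_repeat"
    OFF_TARGET = "off_target"
    NONE = "none"


#: fluorochromes used to label the four probe libraries
FLUOROCHROMES = ("Atto488", "Atto550", "Atto594", "Cy5")


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies fully inside this interval (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Genome:
    """A named assembly: chromosome name -> uppercase DNA over {A,C,G,T,N}."""

    genome_id: str
    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Extract the sequence of an interval; bounds-checked."""
        if interval.chrom not in self.sequences:
            raise KeyError(
                f"chromosome {interval.chrom!r} not in genome {self.genome_id!r}"
            )
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


@dataclass
class Oligo:
    """A candidate probe: a fixed-length window of the source assembly."""

    oligo_id: str
    sequence: str
    origin: GenomicInterval
    gc_fraction: float
    status: OligoStatus = OligoStatus.CANDIDATE
    discard_reason: DiscardReason = DiscardReason.NONE
    fluorochrome: Optional[str] = None
    region_id: Optional[str] = None

    @classmethod
    def from_origin(
        cls,
        sequence: str,
        origin: GenomicInterval,
        fluorochrome: Optional[str] = None,
        region_id: Optional[str] = None,
    ) -> "Oligo":
        L = len(sequence)
        if len(origin) != L:
            raise ValueError("origin span must equal oligo length")
        return cls(
            oligo_id=f"{origin.chrom}:{origin.start}-{origin.end}",
            sequence=sequence,
            origin=origin,
            gc_fraction=gc_count(sequence) / L,
            fluorochrome=fluorochrome,
            region_id=region_id,
        )

    def discarded(self, reason: DiscardReason) -> "Oligo":
        return replace(self, status=OligoStatus.DISCARDED, discard_reason=reason)

    def retained(self) -> "Oligo":
        return replace(self, status=OligoStatus.RETAINED)


@dataclass
class DesignParameters:
    """Every numeric knob of the design pipeline.

    The probe geometry (47-nt oligos tiled with a 3-bp gap), the 30-66%
    GC window, the 32-mer / top-5,000 de novo repeat library, and the
    28-base repeat-overlap discard rule are the published design rules of
    the Brassica A-genome painting toolkit; the remaining fields
    parameterize the internal mapper, peak caller and block clustering.
    """

    oligo_length: int = 47          # L, nt per probe
    gap: int = 3                    # bp between adjacent tiles
    gc_min: float = 30.0            # percent, inclusive
    gc_max: float = 66.0            # percent, inclusive
    kmer_k: int = 32                # de novo repeat k-mer size
    repeat_top_n: int = 5000        # k-mers concatenated into the library
    repeat_overlap_min: int = 28    # bp shared with a repeat library -> discard
    offtarget_max_mismatch: int = 5
    seed_len_self: int = 18
    seed_len_cross: int = 13
    cross_max_mismatch: int = 9     # ~80% identity over 47 nt
    bin_size: int = 100_000         # hybridization-simulation bin
    peak_min_hits_per_bin: int = 5
    block_gap_max: int = 500_000    # synteny-block clustering gap
    block_min_hits: int = 20
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.gc_min < self.gc_max <= 100):
            raise ValueError("need 0 < gc_min < gc_max <= 100")
        if self.oligo_length <= max(self.seed_len_self, 1):
            raise ValueError("oligo_length must exceed seed lengths")
        for name in (
            "gap", "kmer_k", "repeat_top_n", "repeat_overlap_min",
            "offtarget_max_mismatch", "cross_max_mismatch", "bin_size",
            "peak_min_hits_per_bin", "block_gap_max", "block_min_hits",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def period(self) -> int:
        """Tiling period: oligo length plus inter-oligo gap."""
        return self.oligo_length + self.gap


__all__ = [
    "DNA_ALPHABET",
    "FLUOROCHROMES",
    "DesignParameters",
    "DiscardReason",
    "Genome",
    "GenomicInterval",
    "Oligo",
    "OligoStatus",
    "decode",
    "encode",
    "gc_count",
    "normalize_sequence",
    "revcomp",
]
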