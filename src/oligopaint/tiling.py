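"""Candidate generation: tile target regions and apply ambiguity/GC filters.

Probes are taken from the forward strand of the assembly as fixed-length
windows separated by a short gap (default 47 nt + 3 bp), the gap preventing
steric interference between adjacent hybridized probes. Windows touching an
ambiguous base (N) are dropped; the rest must sit inside an inclusive GC
window (default 30-66%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .core import (
    DesignParameters,
    DiscardReason,
    Genome,
    GenomicInterval,
    Oligo,
    OligoStatus,
)


@dataclass
class TilingResult:
    region: GenomicInterval
    candidates: List[Oligo]
    n_skipped_ambiguity: int


def tile_region(
    genome: Genome,
    region: GenomicInterval,
    params: DesignParameters,
    fluorochrome: Optional[str] = None,
    region_id: Optional[str] = None,
) -> TilingResult:
    """Tile *region* into candidate oligos of length L every L+gap bp.

    Tiles start at ``region.start + i*(L+gap)`` while the full window fits
    inside the region; a trailing partial window is never emitted. Windows
    containing N are counted in ``n_skipped_ambiguity`` and excluded.
    """
    L = params.oligo_length
    seq = genome.fetch(region)  # bounds-checked against the chromosome
    candidates: List[Oligo] = []
    n_skipped = 0
    for offset in range(0, len(seq) - L + 1, params.period):
        window = seq[offset : offset + L]
        if "N" in window:
            n_skipped += 1
            continue
        origin = GenomicInterval(
            region.chrom, region.start + offset, region.start + offset + L,
            genome_id=genome.genome_id,
        )
        candidates.append(
            Oligo.from_origin(window, origin, fluorochrome=fluorochrome,
                              region_id=region_id)
        )
    return TilingResult(region=region, candidates=candidates,
                        n_skipped_ambiguity=n_skipped)


def gc_filter(oligos: Sequence[Oligo], params: DesignParameters) -> List[Oligo]:
    """Discard oligos whose GC percentage falls outside [gc_min, gc_max].

    Bounds are inclusive and compared as exact rationals:
    ``gc_min*L <= 100*n_gc <= gc_max*L`` avoids any float-rounding of the
    percentage itself. Order is preserved; already-discarded oligos pass
    through untouched.
    """
    L = params.oligo_length
    out: List[Oligo] = []
    for o in oligos:
        if o.status is OligoStatus.DISCARDED:
            out.append(o)
            continue
        n_gc = round(o.gc_fraction * L)
        if params.gc_min * L <= 100 * n_gc <= params.gc_max * L:
            out.append(o)
        else:
            out.append(o.discarded(DiscardReason.GC))
    return out
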