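"""Genome-specificity mapping: seed-and-verify oligo alignment, the
off-target filter, and cross-species transfer into synteny blocks.

The internal mapper is ungapped: an indel inside a ~47-nt probe effectively
abolishes hybridization, so alignments are scored by Hamming distance only.
Every ``seed_len``-mer of the oligo (both strands) is looked up in a sorted
k-mer index of the genome and candidate placements are verified exactly.
When ``lossless=True`` the seed length is capped at ``floor(L/(m+1))`` for
mismatch budget m, which by pigeonhole guarantees every alignment within
budget contains an exact seed; the cross-species pass keeps its longer seed
as a sensitivity heuristic instead (documented in the methods note).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import (
    DesignParameters,
    DiscardReason,
    Genome,
    GenomicInterval,
    Oligo,
    encode,
    revcomp,
)


@dataclass(frozen=True)
class MapHit:
    oligo_id: str
    location: GenomicInterval
    strand: str  # '+' or '-'
    mismatches: int
    region_id: Optional[str] = None
    fluorochrome: Optional[str] = None
    origin_start: Optional[int] = None


class Orientation(enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    MIXED = "mixed"


@dataclass
class SyntenyBlock:
    block_id: str
    species: str
    location: GenomicInterval
    hits: List[MapHit]
    source_region: str
    orientation: Orientation


def _forward_codes(arr: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes of every k-window plus an N-free validity mask."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_n = (arr == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    codes = np.zeros(n, dtype=np.uint64)
    a = arr & 3
    for j in range(k):
        codes |= a[j : j + n].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
    return codes, valid


class GenomeIndex:
    """Sorted seed-k-mer index over a genome's concatenated chromosomes."""

    def __init__(self, genome: Genome, seed_len: int) -> None:
        if not (1 <= seed_len <= 32):
            raise ValueError("seed_len must be in 1..32")
        self.genome = genome
        self.seed_len = seed_len
        parts: List[np.ndarray] = []
        self.chrom_names: List[str] = []
        self.chrom_offsets: List[int] = []
        self.chrom_lengths: List[int] = []
        sep = np.full(seed_len, 4, dtype=np.uint8)  # N spacer between chroms
        offset = 0
        for name, seq in genome.sequences.items():
            self.chrom_names.append(name)
            self.chrom_offsets.append(offset)
            self.chrom_lengths.append(len(seq))
            parts.append(encode(seq))
            parts.append(sep)
            offset += len(seq) + seed_len
        self.arr = np.concatenate(parts)
        codes, valid = _forward_codes(self.arr, seed_len)
        positions = np.flatnonzero(valid)
        codes = codes[valid]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._positions = positions[order]
        self._offsets_arr = np.array(self.chrom_offsets, dtype=np.int64)
        self._ends_arr = self._offsets_arr + np.array(self.chrom_lengths, dtype=np.int64)

    def seed_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, np.uint64(code), side="left")
        hi = np.searchsorted(self._codes, np.uint64(code), side="right")
        return self._positions[lo:hi]

    def locate(self, gpos: np.ndarray, length: int) -> Tuple[np.ndarray, np.ndarray]:
        """Map global window starts to (chrom index, local start); windows not
        fully inside one chromosome get chrom index -1."""
        ci = np.searchsorted(self._offsets_arr, gpos, side="right") - 1
        ok = (ci >= 0) & (gpos + length <= self._ends_arr[np.clip(ci, 0, None)])
        local = gpos - self._offsets_arr[np.clip(ci, 0, None)]
        return np.where(ok, ci, -1), local


def effective_seed_len(L: int, seed_len: int, max_mismatch: int) -> int:
    """Seed length guaranteeing lossless seeding at the given mismatch budget."""
    return max(1, min(seed_len, L // (max_mismatch + 1)))


def map_oligos(
    oligos: Sequence[Oligo],
    genome: Genome,
    seed_len: int,
    max_mismatch: int,
    lossless: bool = True,
    index: Optional[GenomeIndex] = None,
) -> List[MapHit]:
    """Find every ungapped placement of each oligo with <= max_mismatch
    mismatches, on both strands. Hits are deduplicated and sorted by
    (chrom, start, oligo, strand)."""
    if not oligos:
        return []
    L = len(oligos[0].sequence)
    eff = effective_seed_len(L, seed_len, max_mismatch) if lossless else seed_len
    if index is None or index.seed_len != eff or index.genome is not genome:
        index = GenomeIndex(genome, eff)
    arr = index.arr
    hits: List[MapHit] = []
    win = np.arange(L, dtype=np.int64)
    for oligo in oligos:
        seen = set()
        for strand, seq in (("+", oligo.sequence), ("-", revcomp(oligo.sequence))):
            s_arr = encode(seq)
            codes, valid = _forward_codes(s_arr, eff)
            cand: List[np.ndarray] = []
            for j in np.flatnonzero(valid):
                pos = index.seed_positions(int(codes[j]))
                if pos.size:
                    cand.append(pos.astype(np.int64) - int(j))
            if not cand:
                continue
            starts = np.unique(np.concatenate(cand))
            starts = starts[starts >= 0]
            ci, local = index.locate(starts, L)
            keep = ci >= 0
            starts, ci, local = starts[keep], ci[keep], local[keep]
            if starts.size == 0:
                continue
            sub = arr[starts[:, None] + win]
            mism = (sub != s_arr).sum(axis=1)
            ok = mism <= max_mismatch
            for g, c, loc, m in zip(
                starts[ok], ci[ok], local[ok], mism[ok]
            ):
                key = (int(c), int(loc), strand)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    MapHit(
                        oligo_id=oligo.oligo_id,
                        location=GenomicInterval(
                            index.chrom_names[int(c)], int(loc), int(loc) + L,
                            genome_id=genome.genome_id,
                        ),
                        strand=strand,
                        mismatches=int(m),
                        region_id=oligo.region_id,
                        fluorochrome=oligo.fluorochrome,
                        origin_start=oligo.origin.start,
                    )
                )
    hits.sort(key=lambda h: (h.location.chrom, h.location.start, h.oligo_id, h.strand))
    return hits


@dataclass
class SpecificityResult:
    survivors: List[Oligo]
    discarded: List[Oligo]
    hits: Dict[str, List[MapHit]]  # oligo_id -> hits of surviving oligos


def offtarget_filter(
    oligos: Sequence[Oligo],
    genome: Genome,
    targets: Sequence[GenomicInterval],
    params: DesignParameters,
    hits: Optional[Sequence[MapHit]] = None,
) -> SpecificityResult:
    """Discard any oligo with a hit outside its own target region.

    Hits inside *other* target regions of the same design also count as
    off-target: every band must stay specific to its own chromosomal region.
    Duplications entirely within the oligo's own target are tolerated. A
    pre-computed hit list (e.g. imported from SAM) may be supplied; otherwise
    the internal mapper runs with the self-genome settings.
    """
    if hits is None:
        hits = map_oligos(
            oligos, genome, params.seed_len_self, params.offtarget_max_mismatch,
            lossless=True,
        )
    by_oligo: Dict[str, List[MapHit]] = {}
    for h in hits:
        by_oligo.setdefault(h.oligo_id, []).append(h)
    survivors: List[Oligo] = []
    discarded: List[Oligo] = []
    kept_hits: Dict[str, List[MapHit]] = {}
    for oligo in oligos:
        own = next((t for t in targets if t.contains(oligo.origin)), None)
        if own is None:
            raise ValueError(
                f"oligo {oligo.oligo_id} origin lies in no target region"
            )
        ohits = by_oligo.get(oligo.oligo_id, [])
        if all(own.contains(h.location) for h in ohits):
            survivors.append(oligo.retained())
            kept_hits[oligo.oligo_id] = ohits
        else:
            discarded.append(oligo.discarded(DiscardReason.OFF_TARGET))
    return SpecificityResult(survivors=survivors, discarded=discarded, hits=kept_hits)


@dataclass
class TransferResult:
    blocks: List[SyntenyBlock]
    noise: List[MapHit]
    raw_hits_per_region: Dict[str, int]


def _orientation(block_hits: Sequence[MapHit]) -> Orientation:
    origins = [h.origin_start for h in block_hits if h.origin_start is not None]
    positions = [h.location.start for h in block_hits if h.origin_start is not None]
    if len(origins) < 3 or len(set(origins)) < 2 or len(set(positions)) < 2:
        return Orientation.MIXED
    rho = stats.spearmanr(origins, positions).statistic
    if np.isnan(rho):
        return Orientation.MIXED
    if rho > 0.5:
        return Orientation.FORWARD
    if rho < -0.5:
        return Orientation.REVERSE
    return Orientation.MIXED


def cross_species_transfer(
    oligos: Sequence[Oligo],
    genome2: Genome,
    params: DesignParameters,
) -> TransferResult:
    """Map a retained pool onto a related genome and cluster the hits into
    homoeologous/syntenic blocks.

    Mapping uses the relaxed cross-species settings. Hits are grouped per
    source region and target chromosome, clustered with inter-hit gaps
    <= block_gap_max, and clusters with fewer than block_min_hits hits are
    dropped (their hits are reported as noise). Block orientation is the
    sign of the rank correlation between oligo origin order and hit order.
    """
    hits = map_oligos(
        oligos, genome2, params.seed_len_cross, params.cross_max_mismatch,
        lossless=False,
    )
    raw_counts: Dict[str, int] = {}
    grouped: Dict[Tuple[str, str], List[MapHit]] = {}
    for h in hits:
        region = h.region_id or "unassigned"
        raw_counts[region] = raw_counts.get(region, 0) + 1
        grouped.setdefault((region, h.location.chrom), []).append(h)
    blocks: List[SyntenyBlock] = []
    noise: List[MapHit] = []
    for (region, chrom), ghits in sorted(grouped.items()):
        ghits.sort(key=lambda h: h.location.start)
        clusters: List[List[MapHit]] = [[ghits[0]]]
        for h in ghits[1:]:
            if h.location.start - clusters[-1][-1].location.start <= params.block_gap_max:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        idx = 0
        for cluster in clusters:
            if len(cluster) < params.block_min_hits:
                noise.extend(cluster)
                continue
            span = GenomicInterval(
                chrom,
                cluster[0].location.start,
                max(h.location.end for h in cluster),
                genome_id=genome2.genome_id,
            )
            blocks.append(
                SyntenyBlock(
                    block_id=f"{region}@{genome2.genome_id}:{chrom}.{idx}",
                    species=genome2.genome_id,
                    location=span,
                    hits=cluster,
                    source_region=region,
                    orientation=_orientation(cluster),
                )
            )
            idx += 1
    return TransferResult(blocks=blocks, noise=noise, raw_hits_per_region=raw_counts)


def hits_from_sam(path, oligos: Sequence[Oligo], genome_id: str = "") -> List[MapHit]:
    """Import mapped hits from a SAM file in place of the internal mapper.

    Uses the NM tag for the mismatch count when present. Only primary and
    secondary ungapped alignments of known oligo ids are converted.
    """
    import pysam

    meta = {o.oligo_id: o for o in oligos}
    hits: List[MapHit] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_name not in meta:
                continue
            o = meta[aln.query_name]
            hits.append(
                MapHit(
                    oligo_id=aln.query_name,
                    location=GenomicInterval(
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_start + len(o.sequence),
                        genome_id=genome_id,
                    ),
                    strand="-" if aln.is_reverse else "+",
                    mismatches=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                    region_id=o.region_id,
                    fluorochrome=o.fluorochrome,
                    origin_start=o.origin.start,
                )
            )
    hits.sort(key=lambda h: (h.location.chrom, h.location.start, h.oligo_id, h.strand))
    return hits
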