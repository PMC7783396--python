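"""In-silico FISH: binned hit coverage, signal-peak calling, ideotype band
tables, and cross-genome rearrangement classification.

A predicted FISH signal ("peak") is a run of bins whose probe-hit count
reaches ``peak_min_hits_per_bin``; a single sub-threshold bin inside a run
does not split the signal (one band should not be broken by a binning
artifact). Peak position is the hit-weighted mean coordinate, intensity the
number of contributing hits, width the bin-aligned span.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import DesignParameters, Genome, GenomicInterval
from .mapping import MapHit, Orientation, SyntenyBlock, _orientation

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    genome_id: str
    chrom: str
    bin_size: int
    counts: np.ndarray  # hits per bin; sums to the chromosome's hit count


@dataclass
class HybridizationPeak:
    peak_id: str
    genome_id: str
    chrom: str
    span: GenomicInterval
    intensity: int
    width: int
    position: float  # hit-weighted mean midpoint, bp
    source_region: str
    fluorochrome: Optional[str]
    orientation: Orientation


class CallType(enum.Enum):
    TRANSLOCATION = "translocation"
    FUSION = "fusion"
    DELETION = "deletion"
    REORIENTATION = "reorientation"
    DUPLICATION = "duplication"


@dataclass
class RearrangementCall:
    type: CallType
    source_regions: List[str]
    locations: List[GenomicInterval]
    evidence: List[str]  # peak ids (empty only for deletion)


def _flatten_hits(
    hits_or_blocks: Union[Sequence[MapHit], Sequence[SyntenyBlock]]
) -> List[MapHit]:
    hits: List[MapHit] = []
    for item in hits_or_blocks:
        if isinstance(item, SyntenyBlock):
            hits.extend(item.hits)
        else:
            hits.append(item)
    return hits


def _majority(values: Iterable[Optional[str]]) -> Optional[str]:
    counts: Dict[str, int] = {}
    for v in values:
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda k: counts[k])


def simulate_hybridization(
    hits_or_blocks: Union[Sequence[MapHit], Sequence[SyntenyBlock]],
    genome: Genome,
    params: DesignParameters,
) -> Tuple[List[CoverageProfile], List[HybridizationPeak]]:
    """Bin probe hits per chromosome and call signal peaks.

    Accepts raw map hits or synteny blocks (whose hits are pooled). Returns
    one coverage profile per chromosome of *genome* (possibly all-zero) and
    the called peaks sorted by (chrom, start).
    """
    hits = _flatten_hits(hits_or_blocks)
    bs = params.bin_size
    by_chrom: Dict[str, List[MapHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.location.chrom, []).append(h)
    profiles: List[CoverageProfile] = []
    peaks: List[HybridizationPeak] = []
    for chrom, seq in genome.sequences.items():
        n_bins = (len(seq) + bs - 1) // bs
        counts = np.zeros(n_bins, dtype=np.int64)
        chits = by_chrom.get(chrom, [])
        for h in chits:
            counts[min(h.location.start // bs, n_bins - 1)] += 1
        profiles.append(
            CoverageProfile(genome.genome_id, chrom, bs, counts)
        )
        marked = np.flatnonzero(counts >= params.peak_min_hits_per_bin)
        if marked.size == 0:
            continue
        # group marked bins, tolerating one sub-threshold gap bin
        groups: List[List[int]] = [[int(marked[0])]]
        for b in marked[1:]:
            if int(b) - groups[-1][-1] <= 2:
                groups[-1].append(int(b))
            else:
                groups.append([int(b)])
        for gi, group in enumerate(groups):
            first, last = group[0], group[-1]
            span = GenomicInterval(
                chrom, first * bs, min((last + 1) * bs, len(seq)),
                genome_id=genome.genome_id,
            )
            phits = [
                h for h in chits
                if first <= h.location.start // bs <= last
            ]
            mids = np.array([(h.location.start + h.location.end) / 2 for h in phits])
            peaks.append(
                HybridizationPeak(
                    peak_id=f"{genome.genome_id}:{chrom}.{gi}",
                    genome_id=genome.genome_id,
                    chrom=chrom,
                    span=span,
                    intensity=len(phits),
                    width=len(span),
                    position=float(mids.mean()),
                    source_region=_majority(h.region_id for h in phits) or "unassigned",
                    fluorochrome=_majority(h.fluorochrome for h in phits),
                    orientation=_orientation(phits),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.span.start))
    return profiles, peaks


def coverage_to_bedgraph(
    profiles: Sequence[CoverageProfile], skip_zero: bool = True
) -> List[Tuple[GenomicInterval, int]]:
    rows: List[Tuple[GenomicInterval, int]] = []
    for prof in profiles:
        for b, c in enumerate(prof.counts):
            if skip_zero and c == 0:
                continue
            rows.append(
                (
                    GenomicInterval(
                        prof.chrom, b * prof.bin_size, (b + 1) * prof.bin_size,
                        genome_id=prof.genome_id,
                    ),
                    int(c),
                )
            )
    return rows


def compare_genomes(
    peaks_src: Sequence[HybridizationPeak],
    peaks_dst: Sequence[HybridizationPeak],
    region_map: Optional[Dict[str, str]] = None,
    raw_hits_per_region: Optional[Dict[str, int]] = None,
    params: Optional[DesignParameters] = None,
) -> List[RearrangementCall]:
    """Classify structural differences between two predicted signal sets.

    Both peak sets must derive from the same source design. Per region:
    no destination peak -> deletion (guarded by the raw-hit count when
    available: a region with sub-block-threshold but non-zero hits is logged
    as a weak signal, not called deleted); more than one destination peak ->
    duplication; a single peak on an unexpected chromosome -> translocation;
    reverse orientation -> reorientation. The expected chromosome of each
    source chromosome is the majority destination of its regions' peaks
    (ties broken by the region nearest the chromosome start); two source
    chromosomes sharing one expected destination -> fusion.
    """
    params = params or DesignParameters()
    src_by_region: Dict[str, HybridizationPeak] = {}
    for p in peaks_src:
        cur = src_by_region.get(p.source_region)
        if cur is None or p.intensity > cur.intensity:
            src_by_region[p.source_region] = p
    region_map = region_map or {r: p.chrom for r, p in src_by_region.items()}

    dst_by_region: Dict[str, List[HybridizationPeak]] = {}
    for p in peaks_dst:
        dst_by_region.setdefault(p.source_region, []).append(p)

    # expected destination chromosome per source chromosome (majority vote)
    regions_by_src: Dict[str, List[str]] = {}
    for region, chrom in region_map.items():
        regions_by_src.setdefault(chrom, []).append(region)
    expected: Dict[str, str] = {}
    for src_chrom, regions in regions_by_src.items():
        votes: Dict[str, int] = {}
        for r in regions:
            best = _best_peak(dst_by_region.get(r, []))
            if best is not None:
                votes[best.chrom] = votes.get(best.chrom, 0) + 1
        if not votes:
            continue
        top = max(votes.values())
        tied = sorted(c for c, v in votes.items() if v == top)
        if len(tied) == 1:
            expected[src_chrom] = tied[0]
        else:
            nearest = min(
                (r for r in regions if _best_peak(dst_by_region.get(r, [])) is not None),
                key=lambda r: (
                    src_by_region[r].span.start if r in src_by_region else 0
                ),
            )
            expected[src_chrom] = _best_peak(dst_by_region[nearest]).chrom

    calls: List[RearrangementCall] = []
    order = sorted(
        region_map,
        key=lambda r: (
            region_map[r],
            src_by_region[r].span.start if r in src_by_region else 0,
        ),
    )
    for region in order:
        src_chrom = region_map[region]
        dpeaks = dst_by_region.get(region, [])
        if not dpeaks:
            raw = (raw_hits_per_region or {}).get(region, 0)
            if raw_hits_per_region is not None and raw >= params.block_min_hits:
                logger.warning(
                    "region %s: no peak but %d raw hits — weak signal, "
                    "not called deleted", region, raw,
                )
                continue
            if raw > 0:
                logger.info("region %s: weak residual signal (%d hits)", region, raw)
            calls.append(
                RearrangementCall(CallType.DELETION, [region], [], [])
            )
            continue
        if len(dpeaks) > 1:
            calls.append(
                RearrangementCall(
                    CallType.DUPLICATION, [region],
                    [p.span for p in dpeaks], [p.peak_id for p in dpeaks],
                )
            )
            continue
        peak = dpeaks[0]
        if src_chrom in expected and peak.chrom != expected[src_chrom]:
            calls.append(
                RearrangementCall(
                    CallType.TRANSLOCATION, [region], [peak.span], [peak.peak_id]
                )
            )
        elif peak.orientation is Orientation.REVERSE:
            calls.append(
                RearrangementCall(
                    CallType.REORIENTATION, [region], [peak.span], [peak.peak_id]
                )
            )
    by_dst: Dict[str, List[str]] = {}
    for src_chrom, dst_chrom in expected.items():
        by_dst.setdefault(dst_chrom, []).append(src_chrom)
    for dst_chrom, src_chroms in sorted(by_dst.items()):
        if len(src_chroms) > 1:
            regions = sorted(
                r for c in src_chroms for r in regions_by_src[c]
            )
            evidence = [
                p.peak_id for r in regions for p in dst_by_region.get(r, [])
                if p.chrom == dst_chrom
            ]
            calls.append(
                RearrangementCall(
                    CallType.FUSION, sorted(src_chroms),
                    [p.span for r in regions for p in dst_by_region.get(r, [])
                     if p.chrom == dst_chrom],
                    evidence,
                )
            )
    return calls


def _best_peak(peaks: List[HybridizationPeak]) -> Optional[HybridizationPeak]:
    return max(peaks, key=lambda p: p.intensity) if peaks else None


@dataclass
class IdeotypeBand:
    chrom: str
    fraction: float  # peak position / chromosome length
    color: Optional[str]
    source_region: str


def ideotype_table(
    peaks: Sequence[HybridizationPeak], genome: Genome
) -> List[IdeotypeBand]:
    """Bands (position fraction, color, region) per chromosome, for drawing
    diagrammatic chromosomes with predicted probe signals."""
    bands = [
        IdeotypeBand(
            chrom=p.chrom,
            fraction=p.position / genome.length(p.chrom),
            color=p.fluorochrome,
            source_region=p.source_region,
        )
        for p in peaks
        if p.chrom in genome
    ]
    bands.sort(key=lambda b: (b.chrom, b.fraction))
    return bands


_FLUOR_RGB = {
    "Atto488": "#1faa3c",
    "Atto550": "#d62728",
    "Atto594": "#e6c700",
    "Cy5": "#00b7c3",
}


def render_ideotype(
    bands: Sequence[IdeotypeBand], genome: Genome, path
) -> None:
    """Draw diagrammatic chromosomes with colored probe bands to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(genome.sequences)
    max_len = max(genome.length(c) for c in chroms)
    fig, ax = plt.subplots(figsize=(max(4, len(chroms)), 4))
    for i, chrom in enumerate(chroms):
        h = genome.length(chrom) / max_len
        ax.add_patch(
            plt.Rectangle((i - 0.15, 0), 0.3, h, fill=False, lw=1.2)
        )
        for band in bands:
            if band.chrom != chrom:
                continue
            y = band.fraction * h
            ax.add_patch(
                plt.Rectangle(
                    (i - 0.15, y - 0.01), 0.3, 0.02,
                    color=_FLUOR_RGB.get(band.color or "", "#888888"),
                )
            )
        ax.text(i, -0.06, chrom, ha="center", va="top", fontsize=8)
    ax.set_xlim(-0.6, len(chroms) - 0.4)
    ax.set_ylim(-0.12, 1.05)
    ax.invert_yaxis()
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
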