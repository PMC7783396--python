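"""Design reports, pipeline orchestration, and the flat key-value config.

The design report mirrors the published probe-pool summary format: one row
per (region x genome) with start/end in Mb, oligo count, origin region,
span in kb and oligo density per kb (1 decimal, half-up). A library's size
is the sum of its source-genome rows — transferred rows re-use the same
oligos and are not re-counted — and distinct source sites are counted by
coordinates, since one site may be shared by two libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    DesignParameters,
    DiscardReason,
    Genome,
    GenomicInterval,
    Oligo,
    OligoStatus,
)
from .hybridization import (
    CoverageProfile,
    HybridizationPeak,
    RearrangementCall,
    compare_genomes,
    coverage_to_bedgraph,
    ideotype_table,
    simulate_hybridization,
)
from .io import (
    read_bed_named,
    read_fasta,
    read_reads,
    write_bed,
    write_bedgraph,
    write_oligos_fasta,
    write_tsv,
)
from .mapping import (
    SpecificityResult,
    TransferResult,
    cross_species_transfer,
    map_oligos,
    offtarget_filter,
)
from .repeats import RepeatLibrary, ScreenReport, build_kmer_repeat_library, screen_oligos
from .tiling import gc_filter, tile_region

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "label", "fluorochrome", "start_mb", "end_mb", "n_oligos",
    "chromosome", "origin", "span_kb", "density_per_kb",
]


def density_per_kb(n_oligos: int, span_kb: float) -> float:
    """Oligo density rounded to 1 decimal, half-up (report precision)."""
    d = Decimal(n_oligos) / Decimal(str(span_kb))
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class DesignReport:
    rows: pd.DataFrame              # REPORT_COLUMNS, density recomputed
    library_totals: Dict[str, int]  # fluorochrome -> source-genome oligo sum
    grand_total: int
    n_source_sites: int             # distinct source coordinates
    site_count_min: int
    site_count_max: int

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def build_report(rows: Iterable[dict]) -> DesignReport:
    """Assemble the design report from per-row records.

    Each record needs fluorochrome, start_mb, end_mb, n_oligos, chromosome,
    origin and span_kb (label optional). Density is recomputed; rows where
    ``chromosome == origin`` are the source-genome rows that define library
    sizes and source sites.
    """
    df = pd.DataFrame(list(rows))
    if df.empty:
        return DesignReport(
            rows=pd.DataFrame(columns=REPORT_COLUMNS),
            library_totals={}, grand_total=0, n_source_sites=0,
            site_count_min=0, site_count_max=0,
        )
    if "label" not in df.columns:
        df["label"] = df["fluorochrome"]
    df["density_per_kb"] = [
        density_per_kb(int(n), s) for n, s in zip(df["n_oligos"], df["span_kb"])
    ]
    df = df[REPORT_COLUMNS]
    src = df[df["chromosome"] == df["origin"]]
    totals = {
        fluor: int(g["n_oligos"].sum())
        for fluor, g in src.groupby("fluorochrome")
    }
    sites = src.drop_duplicates(subset=["chromosome", "start_mb", "end_mb"])
    return DesignReport(
        rows=df,
        library_totals=totals,
        grand_total=int(sum(totals.values())),
        n_source_sites=len(sites),
        site_count_min=int(src["n_oligos"].min()),
        site_count_max=int(src["n_oligos"].max()),
    )


def load_design_table() -> pd.DataFrame:
    """The published Brassica A-genome design table bundled with the package."""
    with resources.files("oligopaint.data").joinpath(
        "brassica_design_table.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class TargetRegion:
    interval: GenomicInterval
    region_id: str
    fluorochrome: Optional[str] = None


@dataclass
class StageLedger:
    """Retained/discarded bookkeeping; candidates must always be conserved."""

    n_tiles: int = 0
    n_skipped_ambiguity: int = 0
    n_discarded_gc: int = 0
    n_discarded_known: int = 0
    n_discarded_kmer: int = 0
    n_discarded_off_target: int = 0
    n_retained: int = 0

    def conserved(self) -> bool:
        return self.n_tiles == (
            self.n_retained + self.n_discarded_gc + self.n_discarded_known
            + self.n_discarded_kmer + self.n_discarded_off_target
        )

    def as_rows(self) -> List[Tuple[str, int]]:
        return [
            ("tiles_emitted", self.n_tiles),
            ("windows_skipped_ambiguity", self.n_skipped_ambiguity),
            ("discarded_gc", self.n_discarded_gc),
            ("discarded_known_repeat", self.n_discarded_known),
            ("discarded_kmer_repeat", self.n_discarded_kmer),
            ("discarded_off_target", self.n_discarded_off_target),
            ("retained", self.n_retained),
        ]


@dataclass
class DesignResult:
    params: DesignParameters
    targets: List[TargetRegion]
    retained: List[Oligo]
    discarded: List[Oligo]
    screen_report: Optional[ScreenReport]
    ledger: StageLedger
    profiles_source: List[CoverageProfile]
    peaks_source: List[HybridizationPeak]
    transfers: Dict[str, TransferResult] = field(default_factory=dict)
    peaks_by_genome: Dict[str, List[HybridizationPeak]] = field(default_factory=dict)
    profiles_by_genome: Dict[str, List[CoverageProfile]] = field(default_factory=dict)
    calls_by_genome: Dict[str, List[RearrangementCall]] = field(default_factory=dict)
    report: Optional[DesignReport] = None

    def retained_by_region(self) -> Dict[str, List[Oligo]]:
        out: Dict[str, List[Oligo]] = {}
        for o in self.retained:
            out.setdefault(o.region_id or "unassigned", []).append(o)
        return out


def run_design(
    genome: Genome,
    targets: Sequence[TargetRegion],
    params: Optional[DesignParameters] = None,
    reads: Optional[Iterable[str]] = None,
    known_repeat_seqs: Optional[Sequence[str]] = None,
    secondary_genomes: Optional[Sequence[Genome]] = None,
) -> DesignResult:
    """Run the full design in memory: tile -> GC -> repeat screen ->
    specificity -> hybridization simulation -> (transfer + comparison per
    secondary genome) -> report."""
    params = params or DesignParameters()
    ledger = StageLedger()

    candidates: List[Oligo] = []
    for t in targets:
        tiled = tile_region(genome, t.interval, params,
                            fluorochrome=t.fluorochrome, region_id=t.region_id)
        candidates.extend(tiled.candidates)
        ledger.n_skipped_ambiguity += tiled.n_skipped_ambiguity
    ledger.n_tiles = len(candidates)
    logger.info("tiled %d candidates over %d regions", len(candidates), len(targets))

    after_gc = gc_filter(candidates, params)
    passed_gc = [o for o in after_gc if o.status is not OligoStatus.DISCARDED]
    discarded: List[Oligo] = [o for o in after_gc if o.status is OligoStatus.DISCARDED]
    ledger.n_discarded_gc = len(discarded)

    libraries: List[RepeatLibrary] = []
    if known_repeat_seqs:
        libraries.append(RepeatLibrary.from_known_sequences(known_repeat_seqs))
    if reads is not None:
        libraries.append(build_kmer_repeat_library(reads, params))
    screen_report: Optional[ScreenReport] = None
    if libraries:
        survivors, screen_report = screen_oligos(passed_gc, libraries, params)
        ledger.n_discarded_known = screen_report.n_discarded_known
        ledger.n_discarded_kmer = screen_report.n_discarded_kmer
        discarded.extend(
            o for o in screen_report.discarded
            if o.discard_reason in (DiscardReason.KNOWN_REPEAT, DiscardReason.KMER_REPEAT)
        )
    else:
        survivors = passed_gc

    spec_result = offtarget_filter(
        survivors, genome, [t.interval for t in targets], params
    )
    ledger.n_discarded_off_target = len(spec_result.discarded)
    discarded.extend(spec_result.discarded)
    retained = spec_result.survivors
    ledger.n_retained = len(retained)
    logger.info("retained %d oligos (%s)", len(retained), ledger.as_rows())

    self_hits = [h for hits in spec_result.hits.values() for h in hits]
    profiles_src, peaks_src = simulate_hybridization(self_hits, genome, params)

    result = DesignResult(
        params=params, targets=list(targets), retained=retained,
        discarded=discarded, screen_report=screen_report, ledger=ledger,
        profiles_source=profiles_src, peaks_source=peaks_src,
    )
    for genome2 in secondary_genomes or []:
        transfer = cross_species_transfer(retained, genome2, params)
        profiles2, peaks2 = simulate_hybridization(transfer.blocks, genome2, params)
        calls = compare_genomes(
            peaks_src, peaks2,
            raw_hits_per_region=transfer.raw_hits_per_region, params=params,
        )
        result.transfers[genome2.genome_id] = transfer
        result.profiles_by_genome[genome2.genome_id] = profiles2
        result.peaks_by_genome[genome2.genome_id] = peaks2
        result.calls_by_genome[genome2.genome_id] = calls
    result.report = report_from_result(result, genome)
    return result


def report_from_result(result: DesignResult, genome: Genome) -> DesignReport:
    """Design-report rows from the computed peaks: one source row per target
    region plus one row per surviving transferred block."""
    rows: List[dict] = []
    pools = result.retained_by_region()
    for t in result.targets:
        rows.append(
            dict(
                label=t.fluorochrome or "", fluorochrome=t.fluorochrome or "",
                start_mb=t.interval.start / 1e6, end_mb=t.interval.end / 1e6,
                n_oligos=len(pools.get(t.region_id, [])),
                chromosome=t.region_id, origin=t.region_id,
                span_kb=len(t.interval) / 1e3,
            )
        )
    fluor_by_region = {t.region_id: t.fluorochrome for t in result.targets}
    for genome_id, transfer in result.transfers.items():
        for block in transfer.blocks:
            rows.append(
                dict(
                    label=fluor_by_region.get(block.source_region) or "",
                    fluorochrome=fluor_by_region.get(block.source_region) or "",
                    start_mb=block.location.start / 1e6,
                    end_mb=block.location.end / 1e6,
                    n_oligos=len(block.hits),
                    chromosome=f"{genome_id}:{block.location.chrom}",
                    origin=block.source_region,
                    span_kb=len(block.location) / 1e3,
                )
            )
    return build_report(rows)


# ---------------------------------------------------------------------------
# config-file front end


@dataclass
class PipelineConfig:
    genome: Path
    targets: Path
    out_dir: Path
    reads: Optional[Path] = None
    known_repeats: Optional[Path] = None
    secondary_genomes: Dict[str, Path] = field(default_factory=dict)
    params: DesignParameters = field(default_factory=DesignParameters)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config; '#' starts a comment.

        Recognized keys: genome, targets, out_dir, reads, known_repeats,
        secondary.<genome_id>, and every design-parameter field.
        """
        raw: Dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = value
        for required in ("genome", "targets", "out_dir"):
            if required not in raw:
                raise ValueError(f"config missing required key {required!r}")
        secondary = {
            k.split(".", 1)[1]: Path(v)
            for k, v in raw.items() if k.startswith("secondary.")
        }
        pfields = {f: t for f, t in DesignParameters.__annotations__.items()}
        pkwargs = {}
        for key, value in raw.items():
            if key in pfields:
                typ = float if pfields[key] == "float" else int
                pkwargs[key] = typ(value)
        return cls(
            genome=Path(raw["genome"]),
            targets=Path(raw["targets"]),
            out_dir=Path(raw["out_dir"]),
            reads=Path(raw["reads"]) if "reads" in raw else None,
            known_repeats=Path(raw["known_repeats"]) if "known_repeats" in raw else None,
            secondary_genomes=secondary,
            params=DesignParameters(**pkwargs),
        )


def read_targets_bed(path) -> List[TargetRegion]:
    """BED targets: column 4 names the region, column 5 (if present and
    textual) assigns the fluorochrome."""
    targets: List[TargetRegion] = []
    named = read_bed_named(path)
    extra: Dict[int, Optional[str]] = {}
    with open(path) as fh:
        idx = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            fluor = fields[4] if len(fields) > 4 and fields[4] else None
            extra[idx] = fluor
            idx += 1
    for i, (iv, name) in enumerate(named):
        targets.append(TargetRegion(interval=iv, region_id=name,
                                    fluorochrome=extra.get(i)))
    return targets


def run_pipeline(config: PipelineConfig) -> DesignResult:
    """File-level pipeline: read inputs, run the design, write artifacts.

    Outputs under ``out_dir``: retained probe FASTA, screen/stage TSVs,
    per-genome peak and coverage tracks, transferred-block BED, rearrangement
    calls, the ideotype band table, the design report, and a run log with
    the config echo and stage ledger. Missing inputs fail before any stage.
    """
    for p in [config.genome, config.targets, config.reads, config.known_repeats,
              *config.secondary_genomes.values()]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
    genome = read_fasta(config.genome)
    targets = read_targets_bed(config.targets)
    reads = list(read_reads(config.reads)) if config.reads else None
    known = None
    if config.known_repeats:
        known = list(read_fasta(config.known_repeats).sequences.values())
    secondary = [
        read_fasta(path, genome_id=gid)
        for gid, path in config.secondary_genomes.items()
    ]
    result = run_design(
        genome, targets, config.params, reads=reads,
        known_repeat_seqs=known, secondary_genomes=secondary,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_artifacts(result, genome, out, config)
    return result


def write_artifacts(
    result: DesignResult, genome: Genome, out: Path,
    config: Optional[PipelineConfig] = None,
) -> None:
    write_oligos_fasta(result.retained, out / "retained.fasta")
    write_tsv(
        (
            (o.oligo_id, o.region_id or "", o.discard_reason.value)
            for o in result.discarded
        ),
        ["oligo_id", "region", "discard_reason"],
        out / "discarded.tsv",
    )
    write_tsv(result.ledger.as_rows(), ["stage", "count"], out / "stage_ledger.tsv")
    _write_peaks(result.peaks_source, out / "peaks_source.tsv")
    write_bedgraph(
        coverage_to_bedgraph(result.profiles_source), out / "coverage_source.bedgraph"
    )
    bands = ideotype_table(result.peaks_source, genome)
    write_tsv(
        ((b.chrom, f"{b.fraction:.4f}", b.color or "", b.source_region) for b in bands),
        ["chrom", "fraction", "fluorochrome", "source_region"],
        out / "ideotype_source.tsv",
    )
    for gid, transfer in result.transfers.items():
        write_bed(
            ((b.location, f"{b.source_region}|{b.orientation.value}") for b in transfer.blocks),
            out / f"blocks_{gid}.bed",
        )
        _write_peaks(result.peaks_by_genome[gid], out / f"peaks_{gid}.tsv")
        write_bedgraph(
            coverage_to_bedgraph(result.profiles_by_genome[gid]),
            out / f"coverage_{gid}.bedgraph",
        )
        write_tsv(
            (
                (
                    c.type.value, ";".join(c.source_regions),
                    ";".join(f"{l.chrom}:{l.start}-{l.end}" for l in c.locations),
                    ";".join(c.evidence),
                )
                for c in result.calls_by_genome[gid]
            ),
            ["type", "source_regions", "locations", "evidence"],
            out / f"calls_{gid}.tsv",
        )
    if result.report is not None:
        result.report.to_tsv(out / "design_report.tsv")
    lines = ["oligopaint run log"]
    if config is not None:
        lines.append(f"genome = {config.genome}")
        lines.append(f"targets = {config.targets}")
        for k, v in vars(config.params).items():
            lines.append(f"param {k} = {v}")
        if not config.secondary_genomes:
            lines.append("no secondary genome configured: transfer/compare skipped")
    lines += [f"{stage} = {count}" for stage, count in result.ledger.as_rows()]
    (out / "run.log").write_text("\n".join(lines) + "\n")


def _write_peaks(peaks: Sequence[HybridizationPeak], path) -> None:
    write_tsv(
        (
            (
                p.peak_id, p.chrom, p.span.start, p.span.end, p.intensity,
                p.width, f"{p.position:.1f}", p.source_region,
                p.fluorochrome or "", p.orientation.value,
            )
            for p in peaks
        ),
        ["peak_id", "chrom", "start", "end", "intensity", "width",
         "position", "source_region", "fluorochrome", "orientation"],
        path,
    )
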