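"""Readers and writers for FASTA, FASTQ, BED, bedGraph and TSV reports.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; sequences are
normalized on the way in (uppercase, non-ACGT -> N). BED and bedGraph are
plain tab-separated text, 0-based half-open, written and read directly.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple, Union

from Bio import SeqIO

from .core import Genome, GenomicInterval, Oligo, normalize_sequence

PathLike = Union[str, Path]


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


class FormatError(ValueError):
    """Raised on malformed input files."""


def read_fasta(path: PathLike, genome_id: str = "") -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased and any character outside {A,C,G,T} becomes N.
    Records keep file order; duplicate headers are an error.
    """
    genome_id = genome_id or Path(path).stem
    sequences: dict = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise FormatError(f"duplicate FASTA header: {record.id!r}")
            sequences[record.id] = normalize_sequence(str(record.seq))
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(genome_id=genome_id, sequences=sequences)


def write_fasta(records: Iterable[Tuple[str, str]], path: PathLike, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_oligos_fasta(oligos: Sequence[Oligo], path: PathLike) -> None:
    """Export oligos with their origin coordinates in the headers."""
    write_fasta(
        ((f"{o.origin.chrom}:{o.origin.start}-{o.origin.end}", o.sequence) for o in oligos),
        path,
    )


def read_reads(path: PathLike) -> Iterator[str]:
    """Yield normalized read sequences from FASTA or FASTQ (optionally gzipped).

    Qualities are ignored: the repeat k-mer library only needs abundances.
    """
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            yield normalize_sequence(str(record.seq))


def read_bed(path: PathLike, genome_id: str = "") -> List[GenomicInterval]:
    """Read a >=3 column BED file; the optional 4th column names the region.

    Intervals come back in file order (no implicit sorting); the name is
    attached as ``interval.name`` via a lightweight subclass-free convention:
    a parallel list is impractical, so we return intervals and stash names in
    :func:`read_bed_named` instead.
    """
    return [iv for iv, _ in read_bed_named(path, genome_id)]


def read_bed_named(path: PathLike, genome_id: str = "") -> List[Tuple[GenomicInterval, str]]:
    """Read BED rows as (interval, name) pairs; name defaults to chrom:start-end."""
    out: List[Tuple[GenomicInterval, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            out.append((GenomicInterval(chrom, start, end, genome_id), name))
    return out


def write_bed(rows: Iterable[Tuple[GenomicInterval, str]], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for iv, name in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_bedgraph(
    values: Sequence[Tuple[GenomicInterval, float]], path: PathLike
) -> None:
    """Write (interval, value) pairs as 4-column bedGraph.

    Intervals must be sorted and non-overlapping within each chromosome.
    """
    last_end: dict = {}
    for iv, _ in values:
        if iv.start < last_end.get(iv.chrom, 0):
            raise ValueError(
                f"overlapping/unsorted bedGraph intervals at {iv.chrom}:{iv.start}"
            )
        last_end[iv.chrom] = iv.end
    with open(path, "wt") as fh:
        for iv, value in values:
            v = int(value) if float(value).is_integer() else value
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v}\n")


def read_bedgraph(path: PathLike, genome_id: str = "") -> List[Tuple[GenomicInterval, float]]:
    out: List[Tuple[GenomicInterval, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append(
                (GenomicInterval(chrom, int(start), int(end), genome_id), float(value))
            )
    return out


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path: PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
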