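"""Coordinate conventions, coverage containers and light-weight file I/O.

Internally every interval is 0-based half-open, the convention of the
BED-family formats.  FlyBase-style region strings ("2R:7415804..7417265")
are 1-based fully-inclusive and are converted on parse/format, so printed
coordinates round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "BarcodeSpec",
    "RegionParseError",
    "BedGraphFormatError",
    "parse_region_string",
    "format_region_string",
    "interval_length_kb",
    "read_bedgraph",
    "write_bedgraph",
    "rpm_normalize",
    "demultiplex_reads",
    "demultiplex_fastq",
    "read_fasta",
    "write_fasta",
]


class RegionParseError(ValueError):
    """Raised when a region string does not follow ``chrom:a..b``."""


class BedGraphFormatError(ValueError):
    """Raised on malformed or overlapping bedGraph records."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored span, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome or contig name.
    start, end : int
        0-based inclusive start and exclusive end; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length_bp(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __str__(self) -> str:
        return format_region_string(self)


_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<a>\d+)\.\.(?P<b>\d+)$")


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive region string such as ``2R:7415804..7417265``.

    Returns the equivalent 0-based half-open :class:`GenomicInterval`, so the
    1462 bp deletion printed as ``2R:7415804..7417265`` comes back with
    ``length_bp() == 1462``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        if ".." not in text:
            raise RegionParseError(
                f"missing '..' separator in region string {text!r}"
            )
        raise RegionParseError(f"malformed region string {text!r}")
    a, b = int(m.group("a")), int(m.group("b"))
    if a < 1:
        raise RegionParseError(f"1-based start must be >= 1, got {a} in {text!r}")
    if b < a:
        raise RegionParseError(f"reversed bounds {a}..{b} in {text!r}")
    return GenomicInterval(m.group("chrom"), a - 1, b)


def format_region_string(iv: GenomicInterval) -> str:
    """Inverse of :func:`parse_region_string` (1-based inclusive output)."""
    return f"{iv.chrom}:{iv.start + 1}..{iv.end}"


def interval_length_kb(iv: GenomicInterval, decimals: int = 1) -> float:
    """Interval length in kb, rounded half-away-from-zero.

    Half-away-from-zero (not banker's) rounding keeps descriptions such as
    "1.5 kb" deterministic: 1462 bp -> 1.5 at one decimal.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(iv.length_bp()) / Decimal(1000)).quantize(q, ROUND_HALF_UP)
    return float(val)


@dataclass
class CoverageTrack:
    """Fixed-bin coverage on one chromosome.

    Bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``.  Values are
    non-negative; ``normalization`` is ``"raw"`` (read counts) or ``"rpm"``
    (reads per million).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.normalization not in {"raw", "rpm"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def extent_bp(self) -> int:
        return self.n_bins * self.bin_size

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, i * self.bin_size, (i + 1) * self.bin_size)

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size

    def slice_bins(self, iv: GenomicInterval) -> tuple[int, int]:
        """Half-open bin index range covering every bin overlapping `iv`."""
        lo = iv.start // self.bin_size
        hi = -(-iv.end // self.bin_size)
        return max(lo, 0), min(hi, self.n_bins)


def rpm_normalize(track: CoverageTrack, total_reads: int) -> CoverageTrack:
    """Scale a raw track to reads per million sequenced reads."""
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    return CoverageTrack(
        chrom=track.chrom,
        bin_size=track.bin_size,
        values=track.values * (1e6 / total_reads),
        normalization="rpm",
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a binned track as 4-column bedGraph, run-length merging equal
    adjacent bins and omitting zero runs."""
    with open(path, "w") as fh:
        vals = track.values
        i = 0
        n = vals.size
        while i < n:
            j = i
            while j < n and vals[j] == vals[i]:
                j += 1
            if vals[i] != 0:
                fh.write(
                    f"{track.chrom}\t{i * track.bin_size}\t{j * track.bin_size}"
                    f"\t{vals[i]:g}\n"
                )
            i = j


def read_bedgraph(
    path: str | Path,
    bin_size: int,
    n_bins: int | None = None,
    chrom: str | None = None,
) -> CoverageTrack:
    """Read a 4-column bedGraph into a fixed-bin :class:`CoverageTrack`.

    Records must be aligned to the bin grid and non-overlapping; positions
    not covered by any record read as 0.  ``n_bins`` declares the track
    extent (inferred from the furthest record end when omitted).
    """
    records: list[tuple[int, int, float]] = []
    seen_chrom: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedGraphFormatError(
                    f"line {lineno}: expected 4 columns, got {len(fields)}"
                )
            c, s, e, v = fields
            if chrom is not None and c != chrom:
                continue
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise BedGraphFormatError(
                    f"line {lineno}: multiple chromosomes in single-track read "
                    f"({seen_chrom!r} then {c!r}); pass chrom= to select one"
                )
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise BedGraphFormatError(f"line {lineno}: {exc}") from exc
            if start % bin_size or end % bin_size:
                raise BedGraphFormatError(
                    f"line {lineno}: record [{start}, {end}) not aligned to "
                    f"{bin_size} bp bins"
                )
            if records and start < records[-1][1]:
                raise BedGraphFormatError(
                    f"line {lineno}: record [{start}, {end}) overlaps or is "
                    f"out of order with previous record"
                )
            records.append((start, end, value))
    if n_bins is None:
        n_bins = records[-1][1] // bin_size if records else 0
    values = np.zeros(n_bins, dtype=float)
    for start, end, value in records:
        values[start // bin_size : end // bin_size] = value
    return CoverageTrack(
        chrom=seen_chrom if seen_chrom is not None else (chrom or "chr"),
        bin_size=bin_size,
        values=values,
    )


@dataclass(frozen=True)
class BarcodeSpec:
    """A demultiplexing barcode: sample name plus fixed-length barcode."""

    sample: str
    barcode: str

    def __post_init__(self) -> None:
        if not self.barcode or set(self.barcode.upper()) - set("ACGT"):
            raise ValueError(f"barcode must be non-empty ACGT, got {self.barcode!r}")


FastqRead = tuple[str, str, str]  # (name, sequence, quality)


def _validate_specs(specs: Iterable[BarcodeSpec]) -> list[BarcodeSpec]:
    specs = list(specs)
    if not specs:
        raise ValueError("at least one barcode spec required")
    k = len(specs[0].barcode)
    if any(len(s.barcode) != k for s in specs):
        raise ValueError("all barcodes must have the same length")
    codes = [s.barcode.upper() for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcodes in specs")
    if len({s.sample for s in specs}) != len(specs):
        raise ValueError("duplicate sample names in specs")
    return specs


def demultiplex_reads(
    reads: Iterable[FastqRead], specs: Iterable[BarcodeSpec]
) -> dict[str, list[FastqRead]]:
    """Assign reads to samples by exact match of the leading barcode bases.

    The barcode (first ``k`` bases) is trimmed from assigned reads; reads
    matching no barcode go to the ``"unassigned"`` stream untrimmed.  Every
    input read appears in exactly one output stream.
    """
    specs = _validate_specs(specs)
    k = len(specs[0].barcode)
    lookup = {s.barcode.upper(): s.sample for s in specs}
    out: dict[str, list[FastqRead]] = {s.sample: [] for s in specs}
    out["unassigned"] = []
    for name, seq, qual in reads:
        sample = lookup.get(seq[:k].upper()) if len(seq) >= k else None
        if sample is None:
            out["unassigned"].append((name, seq, qual))
        else:
            out[sample].append((name, seq[k:], qual[k:]))
    return out


def _iter_fastq(handle: IO[str]) -> Iterator[FastqRead]:
    from Bio import SeqIO

    for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(handle):
        yield title, seq, qual


def demultiplex_fastq(
    fastq_path: str | Path,
    specs: Iterable[BarcodeSpec],
    outdir: str | Path,
) -> dict[str, int]:
    """File-based demultiplexing: writes one FASTQ per sample plus
    ``unassigned.fastq``; returns per-stream read counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(fastq_path) as fh:
        streams = demultiplex_reads(_iter_fastq(fh), specs)
    counts = {}
    for sample, reads in streams.items():
        with open(outdir / f"{sample}.fastq", "w") as out:
            for name, seq, qual in reads:
                out.write(f"@{name}\n{seq}\n+\n{qual}\n")
        counts[sample] = len(reads)
    return counts


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file into a name -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
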