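"""IUPAC consensus-site census around peak centers.

Peaks nominated as candidate Polycomb response elements are scanned, in a
1 kb window centered on the summit, for consensus binding sites of the
PRE-associated DNA binders (Pho, Zeste, Spps, Dsp1, Grh) and the short
GAGA and GTGT motifs.  Peaks lacking any GAGA site are flagged, since the
GAGA motif is considered a core component of canonical PREs.

The shipped motif strings are editable literature consensus choices, not
ground truth: every census records the exact strings it used, and callers
can supply their own :class:`MotifDef` set (or a TSV of name/pattern rows).
Overlapping matches are all counted; no collapsing rule is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .core_io import GenomicInterval
from .peaks import Peak

__all__ = [
    "MotifDef",
    "MotifHit",
    "MotifCensus",
    "DEFAULT_MOTIFS",
    "reverse_complement",
    "window_around_center",
    "scan_iupac",
    "census_peaks",
    "read_motif_tsv",
    "write_motif_tsv",
    "write_census_tsv",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC consensus pattern, with a free-text source note."""

    name: str
    pattern: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"invalid IUPAC letters {sorted(bad)} in pattern "
                f"{self.pattern!r} for motif {self.name!r}"
            )


# Editable defaults.  The consensus strings are this package's documented
# literature choices; an analysis should report them alongside its counts.
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("Pho", "GCCAT", "Pho/YY1 core consensus"),
    MotifDef("GAGA", "GAGAG", "GAF/Trl GAGA element"),
    MotifDef("GTGT", "GTGT", "GTGT motif enriched at PREs"),
    MotifDef("Zeste", "YGAGYG", "Zeste consensus"),
    MotifDef("Spps", "GGGCGG", "Sp/KLF GC-box (Spps)"),
    MotifDef("Dsp1", "GAAAA", "Dsp1/HMGB pentamer"),
    MotifDef("Grh", "WCCGGTT", "Grainy head consensus core"),
)


@dataclass(frozen=True)
class MotifHit:
    """A single match: 0-based plus-strand start, strand, plus-strand text."""

    position: int
    strand: str
    matched: str


@dataclass
class MotifCensus:
    """Per-peak motif counts over the scan window."""

    peak_id: str
    window: GenomicInterval
    counts: dict[str, int]
    hits: dict[str, list[MotifHit]]
    lacks_gaga: bool


def window_around_center(peak: Peak, half_width: int = 500,
                         chrom_length: int | None = None) -> GenomicInterval:
    """The scan window: ``half_width`` bp either side of the peak summit,
    clipped to chromosome bounds."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    start = max(peak.summit - half_width, 0)
    end = peak.summit + half_width
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(peak.interval.chrom, start, end)


def _compile(pattern: str) -> re.Pattern:
    # N in the *sequence* matches nothing: character classes never include N
    body = "".join(f"[{IUPAC[ch]}]" for ch in pattern.upper())
    return re.compile(f"(?=({body}))")


def scan_iupac(
    seq: str, motif: MotifDef, both_strands: bool = True
) -> list[MotifHit]:
    """All (overlapping) matches of an IUPAC pattern in ``seq``.

    Minus-strand hits are matches of the reverse-complement pattern,
    reported at their plus-strand start coordinate with the plus-strand
    text.  Hits are ordered by position, plus strand first on ties.
    """
    seq = seq.upper()
    hits = [
        MotifHit(m.start(), "+", m.group(1))
        for m in _compile(motif.pattern).finditer(seq)
    ]
    if both_strands:
        rc = reverse_complement(motif.pattern)
        if rc != motif.pattern.upper():  # palindromes: don't double count
            hits += [
                MotifHit(m.start(), "-", m.group(1))
                for m in _compile(rc).finditer(seq)
            ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence slice from a dict-like genome or a pyfaidx.Fasta."""
    record = genome[chrom]
    if isinstance(record, str):
        return record[start:end].upper()
    return str(record[start:end]).upper()


def census_peaks(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    motif_set: Sequence[MotifDef] = DEFAULT_MOTIFS,
    half_width: int = 500,
    both_strands: bool = True,
) -> list[MotifCensus]:
    """One census row per peak, in input order.

    ``lacks_gaga`` is true iff the motif named "GAGA" (if present in the
    set) has zero hits in the peak's window.
    """
    rows = []
    for peak in peaks:
        chrom = peak.interval.chrom
        try:
            record = genome[chrom]
        except KeyError as exc:
            raise LookupError(
                f"chromosome {chrom!r} absent from genome while scanning "
                f"peak at {peak.interval}"
            ) from exc
        chrom_len = len(record)
        win = window_around_center(peak, half_width, chrom_length=chrom_len)
        seq = _fetch(genome, chrom, win.start, win.end)
        hits = {m.name: scan_iupac(seq, m, both_strands) for m in motif_set}
        counts = {name: len(h) for name, h in hits.items()}
        rows.append(
            MotifCensus(
                peak_id=str(peak.interval),
                window=win,
                counts=counts,
                hits=hits,
                lacks_gaga=counts.get("GAGA", 0) == 0,
            )
        )
    return rows


def read_motif_tsv(path: str | Path) -> list[MotifDef]:
    """Motif set from TSV with header columns name, pattern[, source]."""
    motifs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or not f[0]:
                continue
            motifs.append(
                MotifDef(
                    f[idx["name"]],
                    f[idx["pattern"]],
                    f[idx["source"]] if "source" in idx and len(f) > idx["source"] else "",
                )
            )
    return motifs


def write_motif_tsv(motifs: Sequence[MotifDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tpattern\tsource\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\t{m.source}\n")


def write_census_tsv(
    rows: Sequence[MotifCensus], path: str | Path,
    motif_set: Sequence[MotifDef] = DEFAULT_MOTIFS,
) -> None:
    """Census table mirroring the per-peak count layout: one row per peak,
    one column per motif, plus the lacks_GAGA flag."""
    names = [m.name for m in motif_set]
    with open(path, "w") as fh:
        fh.write("peak\twindow\t" + "\t".join(names) + "\tlacks_GAGA\n")
        for r in rows:
            vals = "\t".join(str(r.counts.get(n, 0)) for n in names)
            fh.write(f"{r.peak_id}\t{r.window}\t{vals}\t{int(r.lacks_gaga)}\n")
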