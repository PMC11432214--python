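"""Mapped full-length transcript alignments and their file formats.

A transcript is a strand-aware interval on the circular reference, with the
polyA tail already trimmed (its length kept as metadata).  Supported
formats: BED6 (0-based half-open; converted on load) and a plain TSV
dialect (``id, strand, start, end, polyA_len``; 1-based closed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

from . import coords


@dataclass
class TranscriptAlignment:
    """One mapped full-length transcript."""

    id: str
    strand: str  # J | N
    start: int  # 1-based inclusive, J-strand reference
    end: int
    wraps_origin: bool = False
    polyA_len: int = 0

    def length(self, genome_length: int) -> int:
        return coords.span_length(self.start, self.end, genome_length, self.wraps_origin)

    def span(self) -> Tuple[int, int, bool]:
        return (self.start, self.end, self.wraps_origin)

    def bio_ends(self) -> Tuple[int, int]:
        """(5' genomic position, 3' genomic position).

        For N-strand transcripts the biological 5' end is the higher
        J-strand coordinate (the end field), independent of wrapping.
        """
        if self.strand == "N":
            return self.end, self.start
        return self.start, self.end

    def validate(self, genome_length: int) -> None:
        coords.check_position(self.start, genome_length)
        coords.check_position(self.end, genome_length)
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.id}: strand must be J or N, got {self.strand!r}")
        if self.start > self.end and not self.wraps_origin:
            raise ValueError(f"{self.id}: start > end without wraps_origin")


# ---------------------------------------------------------------------------
# polyA handling for raw (untrimmed) inputs


def trim_polya(seq: str, min_run: int = 5, slack: int = 2) -> Tuple[str, int]:
    """Strip a trailing adenosine run from a raw transcript sequence.

    A run of at least ``min_run`` A's ending within ``slack`` nt of the 3'
    end is removed; returns ``(trimmed_seq, polyA_len)``.  Sequences from
    lima-processed FLNC reads are already trimmed and pass through intact.
    """
    s = seq.upper()
    n = len(s)
    tail_start = None
    i = n - 1
    skipped = 0
    while i >= 0 and skipped <= slack:
        if s[i] == "A":
            j = i
            while j >= 0 and s[j] == "A":
                j -= 1
            if i - j >= min_run:
                tail_start = j + 1
            break
        skipped += 1
        i -= 1
    if tail_start is None:
        return seq, 0
    return seq[:tail_start], n - tail_start


# ---------------------------------------------------------------------------
# I/O


def read_bed6(path, genome_length: int, chrom: Optional[str] = None) -> List[TranscriptAlignment]:
    """Load transcripts from BED6 (0-based half-open, +/- strand).

    ``+`` maps to the J strand, ``-`` to N.  An interval whose end exceeds
    the genome length is interpreted as wrapping the origin (the BED way of
    writing a circular feature as a single line).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED6 line with {len(parts)} fields: {line!r}")
            c, s, e, name, _score, strand = parts[:6]
            if chrom is not None and c != chrom:
                continue
            s1 = int(s) + 1
            e1 = int(e)
            wraps = False
            if e1 > genome_length:
                e1 = e1 - genome_length
                wraps = True
            t = TranscriptAlignment(
                id=name,
                strand="J" if strand == "+" else "N",
                start=s1,
                end=e1,
                wraps_origin=wraps,
            )
            t.validate(genome_length)
            out.append(t)
    return out


def write_bed6(
    transcripts: Iterable[TranscriptAlignment],
    path,
    genome_length: int,
    chrom: str = "ChrM",
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            end = t.end + genome_length if t.wraps_origin else t.end
            strand = "+" if t.strand == "J" else "-"
            fh.write(f"{chrom}\t{t.start - 1}\t{end}\t{t.id}\t0\t{strand}\n")


def read_transcript_tsv(path, genome_length: int) -> List[TranscriptAlignment]:
    """Load transcripts from the 1-based closed TSV dialect."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            start = int(row["start"])
            end = int(row["end"])
            wraps = str(row.get("wraps_origin", "")).lower() in ("1", "true", "yes")
            if start > end:
                wraps = True
            t = TranscriptAlignment(
                id=row["id"],
                strand=row["strand"],
                start=start,
                end=end,
                wraps_origin=wraps,
                polyA_len=int(row.get("polyA_len") or 0),
            )
            t.validate(genome_length)
            out.append(t)
    return out


def write_transcript_tsv(transcripts: Iterable[TranscriptAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "strand", "start", "end", "wraps_origin", "polyA_len"])
        for t in transcripts:
            w.writerow(
                [t.id, t.strand, t.start, t.end, int(t.wraps_origin), t.polyA_len]
            )


def load_transcripts(path, genome_length: int) -> List[TranscriptAlignment]:
    """Dispatch on file extension (.bed -> BED6, otherwise TSV)."""
    p = Path(path)
    if p.suffix.lower() == ".bed":
        return read_bed6(p, genome_length)
    return read_transcript_tsv(p, genome_length)
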