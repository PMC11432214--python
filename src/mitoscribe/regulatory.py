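"""Regulatory inference: TIS/TTS candidates from transcript-end pileups,
control-region motif scanning, CR repeat detection, and assembly of a
whole-genome transcriptional model summary.

Transcription initiation (TIS) and termination (TTS) sites are the only
transcript-end positions that gene boundaries cannot explain: 5'-end
pileups of non-degraded transcripts away from any annotated boundary are
TIS candidates, 3'-end pileups TTS candidates, flagged when they fall
inside a control region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import coords
from .annotation import MitoAnnotation, revcomp
from .classify import ClassifiedTranscript
from .coverage import CoverageTrack


@dataclass
class SiteCall:
    position: int
    strand: str
    end_type: str  # five_prime | three_prime
    support: int
    in_CR: Optional[str] = None
    call: Optional[str] = None  # TIS_candidate | TTS_candidate


@dataclass
class MotifHit:
    motif_class: str  # polyA_run | polyT_run | GA_n_T | A_T_n | TA_repeat | stem_loop
    start: int  # 1-based within the scanned sequence
    end: int
    detail: str = ""


@dataclass
class RepeatPair:
    posA: int
    posB: int
    length: int
    identity: float


# ---------------------------------------------------------------------------
# End pileups and site calls


def _boundary_positions(annotation: MitoAnnotation) -> List[int]:
    out = []
    for r in annotation.records:  # CR edges count as annotated boundaries too
        out.extend((r.start, r.end))
    return out


def end_pileups(
    classified: Iterable[ClassifiedTranscript],
    annotation: MitoAnnotation,
    min_site_support: int = 3,
    tol: int = 3,
) -> List[SiteCall]:
    """Cluster non-degraded transcript ends not explained by boundaries.

    Ends of degraded transcripts are excluded (their positions reflect
    exonuclease progress, not transcription), as is any pileup within
    ``tol`` of an annotated record boundary (those are cleavage products).
    A 3'-end pileup sitting immediately upstream of a detected same-strand
    5'-end pileup is also excluded: polymerases that read through every
    terminator stop when they run back into their own initiation site, so
    such ends mark the origin of a transcription unit, not a terminator.
    """
    L = annotation.genome_length
    boundaries = _boundary_positions(annotation)
    piles: Dict[Tuple[str, str], List[int]] = {}
    for c in classified:
        if c.label == "degraded":
            continue
        t5, t3 = c.transcript.bio_ends()
        piles.setdefault((c.transcript.strand, "five_prime"), []).append(t5)
        piles.setdefault((c.transcript.strand, "three_prime"), []).append(t3)
    calls: List[SiteCall] = []
    for (strand, end_type), positions in piles.items():
        for pos, support in _cluster(positions, tol, L):
            if support < min_site_support:
                continue
            if any(coords.circular_distance(pos, b, L) <= tol for b in boundaries):
                continue
            calls.append(SiteCall(pos, strand, end_type, support))
    five_by_strand: Dict[str, List[int]] = {}
    for c in calls:
        if c.end_type == "five_prime":
            five_by_strand.setdefault(c.strand, []).append(c.position)
    kept = []
    for c in calls:
        if c.end_type == "three_prime":
            step = 1 if c.strand == "J" else -1
            run_around = coords.wrap_position(c.position + step, L)
            if any(
                coords.circular_distance(run_around, q, L) <= tol
                for q in five_by_strand.get(c.strand, ())
            ):
                continue
        kept.append(c)
    kept.sort(key=lambda s: (s.strand, s.position))
    return kept


def _cluster(positions: Sequence[int], tol: int, L: int) -> List[Tuple[int, int]]:
    counts: Dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    out = []
    while counts:
        pos = max(counts, key=lambda p: (counts[p], -p))
        members = [p for p in counts if coords.circular_distance(p, pos, L) <= tol]
        out.append((pos, sum(counts[p] for p in members)))
        for p in members:
            del counts[p]
    return out


def call_tis_tts(
    pileups: Iterable[SiteCall], annotation: MitoAnnotation
) -> List[SiteCall]:
    """Promote pileups to TIS (5' ends) / TTS (3' ends) candidates and
    annotate control-region membership."""
    L = annotation.genome_length
    out = []
    for p in pileups:
        call = "TIS_candidate" if p.end_type == "five_prime" else "TTS_candidate"
        in_cr = None
        for cr in annotation.crs():
            if coords.overlap_length((p.position, p.position, False), cr.span(), L):
                in_cr = cr.name
                break
        out.append(
            SiteCall(p.position, p.strand, p.end_type, p.support, in_cr, call)
        )
    return out


# ---------------------------------------------------------------------------
# Control-region motif scan


def scan_cr_motifs(
    seq: str,
    min_run: int = 5,
    min_stem: int = 5,
    max_loop: int = 8,
) -> List[MotifHit]:
    """Scan a control-region sequence for its characteristic motifs:
    polyA/polyT runs, G(A)nT, A(T)n, (TA)n repeats, and perfect stem-loops
    (inverted repeats found by reverse-complement self-match; no
    thermodynamic folding).

    Positions are 1-based within ``seq``.  Non-ACGT characters end a match
    but do not raise.
    """
    s = seq.upper().replace("U", "T")
    hits: List[MotifHit] = []
    for m in re.finditer(rf"A{{{min_run},}}", s):
        hits.append(MotifHit("polyA_run", m.start() + 1, m.end(), f"run={m.end() - m.start()}"))
    for m in re.finditer(rf"T{{{min_run},}}", s):
        hits.append(MotifHit("polyT_run", m.start() + 1, m.end(), f"run={m.end() - m.start()}"))
    for m in re.finditer(r"G(A{3,})T", s):
        hits.append(MotifHit("GA_n_T", m.start() + 1, m.end(), f"n={len(m.group(1))}"))
    for m in re.finditer(r"A(T{3,})(?=[^T]|$)", s):
        hits.append(MotifHit("A_T_n", m.start() + 1, m.end(), f"n={len(m.group(1))}"))
    min_units = max(2, -(-min_run // 2))  # at least min_run/2 TA units
    for m in re.finditer(rf"(?:TA){{{min_units},}}", s):
        units = (m.end() - m.start()) // 2
        hits.append(MotifHit("TA_repeat", m.start() + 1, m.end(), f"units={units}"))
    hits.extend(_find_stem_loops(s, min_stem, max_loop))
    hits.sort(key=lambda h: (h.start, h.end, h.motif_class))
    return hits


def _find_stem_loops(s: str, min_stem: int, max_loop: int) -> List[MotifHit]:
    """Perfect inverted repeats: stem >= min_stem, loop <= max_loop."""
    n = len(s)
    hits: List[MotifHit] = []
    claimed: List[Tuple[int, int]] = []
    # longest stems first so maximal hairpins claim their span
    candidates = []
    for i in range(n):
        for loop in range(0, max_loop + 1):
            # extend the stem outward from the loop
            stem = 0
            while (
                i - stem - 1 >= 0
                and i + loop + stem < n
                and s[i - stem - 1] == revcomp(s[i + loop + stem])
                and s[i - stem - 1] in "ACGT"
            ):
                stem += 1
            if stem >= min_stem:
                start = i - stem  # 0-based
                end = i + loop + stem - 1
                candidates.append((stem, loop, start, end))
    candidates.sort(key=lambda c: (-c[0], c[2]))
    for stem, loop, start, end in candidates:
        if any(not (end < a or start > b) for a, b in claimed):
            continue
        claimed.append((start, end))
        hits.append(
            MotifHit("stem_loop", start + 1, end + 1, f"stem={stem},loop={loop}")
        )
    return hits


# ---------------------------------------------------------------------------
# CR repeat detection (exact k-mer seeding + ungapped extension)


def find_cr_repeats(
    genome_seq: str,
    windowA: Tuple[int, int],
    windowB: Tuple[int, int],
    min_len: int = 50,
    min_identity: float = 0.9,
    k: int = 12,
) -> List[RepeatPair]:
    """Maximal ungapped local matches between two genome windows.

    Seeds exact ``k``-mers shared by the windows, extends both directions
    while identity stays at or above ``min_identity``, and reports merged
    maximal pairs of length >= ``min_len``.  Coordinates are 1-based genome
    positions of the repeat starts.
    """
    seqA = genome_seq[windowA[0] - 1 : windowA[1]].upper()
    seqB = genome_seq[windowB[0] - 1 : windowB[1]].upper()
    index: Dict[str, List[int]] = {}
    for i in range(len(seqA) - k + 1):
        index.setdefault(seqA[i : i + k], []).append(i)
    seen_diag: Dict[int, List[Tuple[int, int]]] = {}
    pairs: List[RepeatPair] = []
    for j in range(len(seqB) - k + 1):
        kmer = seqB[j : j + k]
        for i in index.get(kmer, ()):
            diag = j - i
            covered = False
            for s, e in seen_diag.get(diag, ()):
                if s <= i <= e:
                    covered = True
                    break
            if covered:
                continue
            a0, b0, length, matches = _extend(seqA, seqB, i, j, k, min_identity)
            seen_diag.setdefault(diag, []).append((a0, a0 + length - 1))
            if length >= min_len and matches / length >= min_identity:
                pairs.append(
                    RepeatPair(
                        posA=windowA[0] + a0,
                        posB=windowB[0] + b0,
                        length=length,
                        identity=matches / length,
                    )
                )
    pairs.sort(key=lambda p: (-p.length, p.posA))
    return pairs


def _extend(
    seqA: str, seqB: str, i: int, j: int, k: int, min_identity: float
) -> Tuple[int, int, int, int]:
    """Greedy ungapped extension of a seed in both directions.

    Extends while the running identity of the whole alignment stays at or
    above ``min_identity``, then trims mismatching flanks.
    """
    a0, b0 = i, j
    a1, b1 = i + k - 1, j + k - 1
    matches = k

    def ident(m, ln):
        return m / ln

    # extend right
    while a1 + 1 < len(seqA) and b1 + 1 < len(seqB):
        m = matches + (seqA[a1 + 1] == seqB[b1 + 1])
        if ident(m, (a1 + 2 - a0)) < min_identity:
            break
        a1 += 1
        b1 += 1
        matches = m
    # extend left
    while a0 > 0 and b0 > 0:
        m = matches + (seqA[a0 - 1] == seqB[b0 - 1])
        if ident(m, (a1 + 1 - (a0 - 1) + 1) - 1) < min_identity:
            break
        a0 -= 1
        b0 -= 1
        matches = m
    # trim mismatching flanks
    while a1 >= a0 and seqA[a1] != seqB[b1]:
        a1 -= 1
        b1 -= 1
        matches = sum(1 for x in range(a1 - a0 + 1) if seqA[a0 + x] == seqB[b0 + x])
    while a0 <= a1 and seqA[a0] != seqB[b0]:
        a0 += 1
        b0 += 1
        matches = sum(1 for x in range(a1 - a0 + 1) if seqA[a0 + x] == seqB[b0 + x])
    length = a1 - a0 + 1
    return a0, b0, max(length, 0), matches


# ---------------------------------------------------------------------------
# Transcriptional model summary


@dataclass
class StrandModel:
    strand: str
    tis: List[SiteCall] = field(default_factory=list)
    tts: List[SiteCall] = field(default_factory=list)
    fully_transcribed_crs: Dict[str, bool] = field(default_factory=dict)


@dataclass
class TranscriptionModel:
    strands: Dict[str, StrandModel]
    undetected_antisense_blocks: List[List[str]]

    def to_dict(self) -> dict:
        return {
            "strands": {
                s: {
                    "tis": [vars(c) for c in m.tis],
                    "tts": [vars(c) for c in m.tts],
                    "fully_transcribed_crs": m.fully_transcribed_crs,
                }
                for s, m in self.strands.items()
            },
            "undetected_antisense_blocks": self.undetected_antisense_blocks,
        }


def _same_strand_blocks(annotation: MitoAnnotation) -> List[Tuple[str, List[str]]]:
    """Maximal runs of consecutive same-strand genes around the circle."""
    recs = sorted(annotation.genes(), key=lambda r: (r.start, r.end))
    n = len(recs)
    if n == 0:
        return []
    breaks = [i for i in range(n) if recs[i].strand != recs[(i - 1) % n].strand]
    if not breaks:
        return [(recs[0].strand, [r.name for r in recs])]
    blocks = []
    for bi, start in enumerate(breaks):
        stop = breaks[(bi + 1) % len(breaks)]
        names = []
        i = start
        while True:
            names.append(recs[i].name)
            i = (i + 1) % n
            if i == stop:
                break
        blocks.append((recs[start].strand, names))
    return blocks


def build_transcription_model(
    site_calls: Iterable[SiteCall],
    classified: Iterable[ClassifiedTranscript],
    annotation: MitoAnnotation,
    coverage: Optional[Tuple[CoverageTrack, CoverageTrack]] = None,
) -> TranscriptionModel:
    """Assemble the per-strand transcription summary: ordered TIS/TTS lists,
    whether each control region is fully covered by transcription on each
    strand, and which same-strand gene blocks lack any detected antisense
    transcript."""
    classified = list(classified)
    if coverage is None:
        from .coverage import compute_coverage

        coverage = compute_coverage(
            [c.transcript for c in classified], annotation.genome_length
        )
    track = {c.strand: c for c in coverage}
    strands: Dict[str, StrandModel] = {}
    for strand in ("J", "N"):
        m = StrandModel(strand)
        for call in site_calls:
            if call.strand != strand:
                continue
            (m.tis if call.call == "TIS_candidate" else m.tts).append(call)
        m.tis.sort(key=lambda c: c.position)
        m.tts.sort(key=lambda c: c.position)
        for cr in annotation.crs():
            m.fully_transcribed_crs[cr.name] = (
                track[strand].min_over(cr.start, cr.end, cr.wraps_origin) >= 1
            )
        strands[strand] = m

    L = annotation.genome_length
    undetected: List[List[str]] = []
    anti = [c for c in classified if c.label == "antisense"]
    for strand, names in _same_strand_blocks(annotation):
        opposite = "N" if strand == "J" else "J"
        covered = False
        for c in anti:
            if c.transcript.strand != opposite:
                continue
            span = c.transcript.span()
            if any(
                coords.overlap_length(span, annotation.get(n).span(), L) > 0
                for n in names
            ):
                covered = True
                break
        if not covered:
            undetected.append(names)
    return TranscriptionModel(strands, undetected)
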