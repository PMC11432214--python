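"""Transcript classification, polycistron inventory, cleavage-direction
evidence and UTR detection.

Classification follows the logic used for full-length mitochondrial
transcript sets: a transcript's *content* is the genes it covers by more
than half their length (antisense genes fully contained in the span are
always listed, prefixed ``as``); it is *mature* when both biological ends
sit on the boundaries of its terminal sense genes, *polycistronic* when it
carries several genes between boundary-true ends, and *degraded* when an
end falls short, inside a sense gene.  An end extending past the terminal
gene boundary through non-coding or antisense territory is not a
truncation — that is how retained 3' UTRs and control-region read-through
present — but an extension intruding more than ``tol`` into a same-strand
gene is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import coords
from .annotation import GeneRecord, MitoAnnotation
from .transcripts import TranscriptAlignment

#: multi-gene units that mature as single mRNAs (bicistronic mRNAs); any
#: other boundary-true multi-gene transcript is a polycistronic precursor
MATURE_MULTI_UNITS = (
    frozenset(("ATP8", "ATP6")),
    frozenset(("ND4", "ND4L")),
    frozenset(("COI", "ND3")),
)

LABELS = ("mature_mono", "mature_multi", "polycistronic", "antisense", "ncRNA_CR", "degraded")

CONTENT_THRESHOLD = 0.5


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptAlignment
    label: str
    content: List[Tuple[str, bool]] = field(default_factory=list)  # (gene, sense)
    end5_matched: bool = False
    end3_matched: bool = False
    truncation: str = "none"  # none | 5prime | 3prime | both
    cr_flank: Tuple[Optional[str], Optional[str]] = (None, None)  # CR at 5'/3' overhang

    @property
    def content_names(self) -> List[str]:
        """Gene names in 5'->3' order, antisense prefixed ``as``; CRs the
        ends read into are appended with a ``*`` (unaligned-end notation)."""
        names = [(n if sense else f"as{n}") for n, sense in self.content]
        cr5, cr3 = self.cr_flank
        if cr5:
            names.insert(0, f"{cr5}*")
        if cr3:
            names.append(f"{cr3}*")
        return names

    @property
    def signature(self) -> str:
        return "/".join(self.content_names)

    def sense_genes(self) -> List[str]:
        return [n for n, sense in self.content if sense]


def _directed_offset(frm: int, to: int, L: int) -> int:
    """Steps from ``frm`` to ``to`` walking in transcription direction,
    reported in ``(-L/2, L/2]`` so short backward offsets stay negative."""
    d = (to - frm) % L
    if d > L // 2:
        d -= L
    return d


class _Annot:
    """Precomputed lookups reused across many classifications."""

    def __init__(self, annotation: MitoAnnotation):
        self.annotation = annotation
        self.L = annotation.genome_length
        self.genes = annotation.genes()
        self.crs = annotation.crs()
        self.gene_len = {g.name: g.length(self.L) for g in self.genes}


_CACHE: Dict[int, _Annot] = {}


def _annot(annotation: MitoAnnotation) -> _Annot:
    key = id(annotation)
    if key not in _CACHE or _CACHE[key].annotation is not annotation:
        _CACHE.clear()
        _CACHE[key] = _Annot(annotation)
    return _CACHE[key]


def _overhang_span(t_end: int, boundary: int, side: str, strand: str, L: int):
    """Genomic interval covered by the end overhang (exclusive of the gene)."""
    step = 1 if strand == "J" else -1
    if side == "5":
        lo, hi = t_end, coords.wrap_position(boundary - step, L)
    else:
        lo, hi = coords.wrap_position(boundary + step, L), t_end
    if strand == "N":
        lo, hi = hi, lo
    wraps = lo > hi
    return (lo, hi, wraps)


def _end_check(
    t_end: int,
    terminal: GeneRecord,
    side: str,
    t: TranscriptAlignment,
    A: _Annot,
    tol: int,
) -> Tuple[bool, int, Optional[str]]:
    """Check one biological end against its terminal gene boundary.

    Returns ``(matched, overhang_len, cr_name)`` where ``overhang_len`` is
    how far the end extends past the boundary (a UTR when positive) and
    ``cr_name`` names a control region the overhang reads into, if any.
    """
    L = A.L
    boundary = terminal.five_prime() if side == "5" else terminal.three_prime()
    sign = 1 if t.strand == "J" else -1
    if side == "5":
        short = _directed_offset(boundary, t_end, L) * sign
    else:
        short = _directed_offset(t_end, boundary, L) * sign
    overhang = max(0, -short)
    short = max(0, short)
    if short > tol:
        return False, 0, None
    cr_name = None
    if overhang > 0:
        span = _overhang_span(t_end, boundary, side, t.strand, L)
        if overhang > tol:
            for g in A.genes:
                if g.strand != t.strand or g.name == terminal.name:
                    continue
                if coords.overlap_length(span, g.span(), L) > tol:
                    return False, overhang, None
        for cr in A.crs:
            if coords.overlap_length(span, cr.span(), L) > 0:
                cr_name = cr.name
                break
    return True, overhang, cr_name


def classify_transcript(
    t: TranscriptAlignment, annotation: MitoAnnotation, tol: int = 3
) -> ClassifiedTranscript:
    """Assign exactly one class label to a mapped transcript."""
    A = _annot(annotation)
    L = A.L
    t.validate(L)
    span = t.span()
    t_len = t.length(L)
    t5, t3 = t.bio_ends()

    content: List[Tuple[str, bool]] = []
    best: Optional[GeneRecord] = None
    best_ov = 0
    for g in A.genes:
        ov = coords.overlap_length(span, g.span(), L)
        if ov == 0:
            continue
        sense = g.strand == t.strand
        glen = A.gene_len[g.name]
        if sense and ov > best_ov:
            best, best_ov = g, ov
        if ov > CONTENT_THRESHOLD * glen or (not sense and ov == glen):
            content.append((g.name, sense))
    cr_ov = sum(coords.overlap_length(span, cr.span(), L) for cr in A.crs)

    # order content along the transcript 5'->3' by where each gene's covered
    # part begins; a gene starting upstream of the transcript 5' end enters
    # at offset 0 (its raw modular offset would wrap to ~L)
    def _offset(name: str) -> Tuple[int, int]:
        g = annotation.get(name)
        p = g.five_prime() if g.strand == t.strand else g.three_prime()
        q = g.three_prime() if g.strand == t.strand else g.five_prime()
        if t.strand == "J":
            off, off_exit = (p - t5) % L, (q - t5) % L
        else:
            off, off_exit = (t5 - p) % L, (t5 - q) % L
        if off >= t_len:
            off = 0
        return off, off_exit

    content.sort(key=lambda item: _offset(item[0]))

    if not content:
        if cr_ov > CONTENT_THRESHOLD * t_len:
            return ClassifiedTranscript(t, "ncRNA_CR", [], False, False, "none")
        if best is None:
            return ClassifiedTranscript(t, "degraded", [], False, False, "both")
        m5, _, _ = _end_check(t5, best, "5", t, A, tol)
        m3, _, _ = _end_check(t3, best, "3", t, A, tol)
        trunc = _truncation(m5, m3)
        return ClassifiedTranscript(t, "degraded", [(best.name, True)], m5, m3, trunc)

    sense_names = [n for n, s in content if s]
    if not sense_names:
        first = annotation.get(content[0][0])
        last = annotation.get(content[-1][0])
        m5, _, cr5 = _end_check(t5, first, "5", t, A, tol)
        m3, _, cr3 = _end_check(t3, last, "3", t, A, tol)
        return ClassifiedTranscript(
            t, "antisense", content, m5, m3, _truncation(m5, m3), (cr5, cr3)
        )

    first = annotation.get(sense_names[0])
    last = annotation.get(sense_names[-1])
    m5, _, cr5 = _end_check(t5, first, "5", t, A, tol)
    m3, _, cr3 = _end_check(t3, last, "3", t, A, tol)
    if m5 and m3:
        if len(sense_names) == 1:
            label = "mature_mono"
        elif frozenset(sense_names) in MATURE_MULTI_UNITS:
            label = "mature_multi"
        else:
            label = "polycistronic"
        return ClassifiedTranscript(t, label, content, m5, m3, "none", (cr5, cr3))
    return ClassifiedTranscript(
        t, "degraded", content, m5, m3, _truncation(m5, m3), (cr5, cr3)
    )


def _truncation(m5: bool, m3: bool) -> str:
    if m5 and m3:
        return "none"
    if not m5 and not m3:
        return "both"
    return "5prime" if not m5 else "3prime"


def classify_all(
    transcripts: Iterable[TranscriptAlignment],
    annotation: MitoAnnotation,
    tol: int = 3,
) -> List[ClassifiedTranscript]:
    return [classify_transcript(t, annotation, tol) for t in transcripts]


def tally_polycistron_types(classified: Iterable[ClassifiedTranscript]) -> pd.DataFrame:
    """One row per distinct polycistron content signature per strand."""
    rows: Dict[Tuple[str, str], int] = {}
    for c in classified:
        if c.label != "polycistronic":
            continue
        key = (c.transcript.strand, c.signature)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(s, sig, n) for (s, sig), n in rows.items()],
        columns=["strand", "signature", "count"],
    )
    return df.sort_values(["count", "strand", "signature"], ascending=[False, True, True]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# tRNA cleavage-direction evidence


@dataclass
class CleavageEvidence:
    """Votes for the processing direction at one tRNA junction."""

    junction: Tuple[Optional[str], str, Optional[str]]  # (upstream, tRNA, downstream)
    direction_votes: Dict[str, int] = field(default_factory=lambda: {"reverse": 0, "forward": 0})


def _strand_successor(annotation: MitoAnnotation, gene: GeneRecord, forward: bool) -> Optional[GeneRecord]:
    """Next same-strand gene along transcription direction, skipping CRs and
    opposite-strand genes."""
    recs = sorted(annotation.genes(), key=lambda r: (r.start, r.end))
    same = [r for r in recs if r.strand == gene.strand]
    idx = next(i for i, r in enumerate(same) if r.name == gene.name)
    step = 1 if (gene.strand == "J") == forward else -1
    return same[(idx + step) % len(same)] if len(same) > 1 else None


def cleavage_direction_evidence(
    classified: Iterable[ClassifiedTranscript],
    annotation: MitoAnnotation,
    tol: int = 3,
) -> List[CleavageEvidence]:
    """Tally reverse (3'->5') vs forward (5'->3') tRNA-removal evidence.

    A transcript whose 3' end sits at the cut site flush with the 5'
    boundary of the genomically following same-strand tRNA (which it does
    not contain) votes *reverse*; one whose 5' end sits flush with the 3'
    boundary of the preceding same-strand tRNA votes *forward*.  Two guards
    keep uninformative molecules silent: the flush requirement (so TIS/TTS-
    explained ends do not vote) and the requirement that the transcript
    still spans at least one uncleaved same-strand tRNA junction — a fully
    processed unit (a mature COI/ND3, say) is the end state of either
    processing direction and witnesses neither.
    """
    L = annotation.genome_length
    votes: Dict[Tuple[Optional[str], str, Optional[str]], CleavageEvidence] = {}
    junction_gaps: Dict[str, List[int]] = {}
    for g in annotation.genes():
        if g.category != "tRNA":
            continue
        junction_gaps.setdefault(g.strand, []).append(g.start - 1 if g.start > 1 else L)
        junction_gaps.setdefault(g.strand, []).append(g.end)

    def _has_internal_junction(t: TranscriptAlignment) -> bool:
        p5, _ = t.bio_ends()
        span_len = t.length(L)
        for gap in junction_gaps.get(t.strand, ()):
            off = (gap - p5) % L if t.strand == "J" else (p5 - (gap + 1)) % L
            if 0 <= off < span_len - 1:
                return True
        return False

    def _vote(trna: GeneRecord, direction: str) -> None:
        up = _strand_successor(annotation, trna, forward=False)
        down = _strand_successor(annotation, trna, forward=True)
        key = (up.name if up else None, trna.name, down.name if down else None)
        ev = votes.setdefault(key, CleavageEvidence(key))
        ev.direction_votes[direction] += 1

    for c in classified:
        if c.label not in ("polycistronic", "mature_multi", "mature_mono"):
            continue
        sense = c.sense_genes()
        if not sense:
            continue
        t = c.transcript
        if not _has_internal_junction(t):
            continue
        t5, t3 = t.bio_ends()
        in_content = set(sense)

        last = annotation.get(sense[-1])
        nxt = _strand_successor(annotation, last, forward=True)
        if nxt is not None and nxt.category == "tRNA" and nxt.name not in in_content:
            step = 1 if t.strand == "J" else -1
            cut = coords.wrap_position(nxt.five_prime() - step, L)
            if coords.circular_distance(t3, cut, L) <= tol:
                _vote(nxt, "reverse")

        firstg = annotation.get(sense[0])
        prv = _strand_successor(annotation, firstg, forward=False)
        if prv is not None and prv.category == "tRNA" and prv.name not in in_content:
            step = 1 if t.strand == "J" else -1
            cut = coords.wrap_position(prv.three_prime() + step, L)
            if coords.circular_distance(t5, cut, L) <= tol:
                _vote(prv, "forward")

    return sorted(votes.values(), key=lambda e: e.junction[1])


# ---------------------------------------------------------------------------
# UTR detection


@dataclass
class UtrReport:
    gene: str
    utr5_len: int
    utr3_len: int
    utr3_retained: bool
    polyadenylation_site: Optional[int] = None


def detect_utrs(
    mature: ClassifiedTranscript, annotation: MitoAnnotation, tol: int = 3
) -> UtrReport:
    """Measure UTRs of a mature mRNA against its CDS boundaries."""
    if mature.label not in ("mature_mono", "mature_multi"):
        raise TypeError(f"detect_utrs needs a mature transcript, got {mature.label}")
    sense = mature.sense_genes()
    cats = {annotation.get(n).category for n in sense}
    if "PCG" not in cats:
        raise TypeError("detect_utrs needs a protein-coding (mRNA) transcript")
    A = _annot(annotation)
    t = mature.transcript
    t5, t3 = t.bio_ends()
    first = annotation.get(sense[0])
    last = annotation.get(sense[-1])
    _, utr5, _ = _end_check(t5, first, "5", t, A, tol)
    _, utr3, _ = _end_check(t3, last, "3", t, A, tol)
    retained = utr3 > 0
    pa_site = t3 if t.polyA_len > 0 else None
    return UtrReport("/".join(sense), utr5, utr3, retained, pa_site)


# ---------------------------------------------------------------------------
# Unit assignment (for isoform / degradation analysis)


def transcripts_of_unit(
    classified: Iterable[ClassifiedTranscript],
    unit: Sequence[str],
) -> List[ClassifiedTranscript]:
    """Transcripts attributable to one gene (or mature multi-gene unit):
    mature members plus degradation candidates, excluding precursors that
    carry genes outside the unit."""
    unit_set = set(unit)
    out = []
    for c in classified:
        if c.label in ("polycistronic", "antisense", "ncRNA_CR"):
            continue
        sense = set(c.sense_genes())
        if sense and sense <= unit_set:
            out.append(c)
    return out


def classification_table(classified: Iterable[ClassifiedTranscript]) -> pd.DataFrame:
    rows = []
    for c in classified:
        t = c.transcript
        rows.append(
            {
                "id": t.id,
                "strand": t.strand,
                "start": t.start,
                "end": t.end,
                "label": c.label,
                "content": c.signature,
                "end5_matched": c.end5_matched,
                "end3_matched": c.end3_matched,
                "truncation": c.truncation,
            }
        )
    return pd.DataFrame(rows)
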