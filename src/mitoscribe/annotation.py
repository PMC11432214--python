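"""Circular mitogenome annotation model and transcript-evidence refinement.

The coordinate system is the J-strand reference, 1-based and fully closed.
N-strand genes are stored with ``start <= end`` and ``strand == "N"``;
control regions (category ``CR``) carry no meaningful strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import coords
from .coords import CoordinateError

logger = logging.getLogger(__name__)

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

#: invertebrate mitochondrial start codons (RNA alphabet)
START_CODONS = {"AUG", "AUA", "AUU", "AUC", "GUG", "UUG", "UUA"}
COMPLETE_STOPS = {"UAA", "UAG"}

TRNA_MIN_LEN = 50
TRNA_MAX_LEN = 75

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ReconciliationError(ValueError):
    """Two annotations cannot be compared (gene sets differ)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class GeneRecord:
    """One annotated feature on the circular mitogenome."""

    name: str
    category: str  # PCG | tRNA | rRNA | CR
    strand: str  # J | N  ("." tolerated for CRs)
    start: int  # 1-based, inclusive, J-strand reference
    end: int  # 1-based, inclusive
    start_codon: Optional[str] = None  # RNA triplet, PCGs only
    stop_codon: Optional[str] = None  # 1-3 nt RNA; truncated stops allowed
    wraps_origin: bool = False

    def length(self, genome_length: int) -> int:
        return coords.span_length(self.start, self.end, genome_length, self.wraps_origin)

    def span(self) -> Tuple[int, int, bool]:
        return (self.start, self.end, self.wraps_origin)

    def five_prime(self) -> int:
        """Genomic position of the gene's biological 5' boundary."""
        if self.strand == "N":
            return self.end
        return self.start

    def three_prime(self) -> int:
        if self.strand == "N":
            return self.start
        return self.end

    def is_cr(self) -> bool:
        return self.category == "CR"


def gene_length(record: GeneRecord, genome_length: int) -> int:
    """Length in bp of a (possibly origin-wrapping) gene."""
    return record.length(genome_length)


@dataclass
class MitoAnnotation:
    """A full circular annotation: ordered records plus optional sequence."""

    genome_length: int
    records: List[GeneRecord] = field(default_factory=list)
    genome_seq: Optional[str] = None

    def __post_init__(self) -> None:
        self.sort()
        if self.genome_seq is not None and len(self.genome_seq) != self.genome_length:
            raise ValueError(
                f"genome_seq length {len(self.genome_seq)} != genome_length {self.genome_length}"
            )

    def sort(self) -> None:
        self.records.sort(key=lambda r: (r.start, r.end))

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, name: str) -> GeneRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def genes(self) -> List[GeneRecord]:
        """All non-CR records."""
        return [r for r in self.records if not r.is_cr()]

    def crs(self) -> List[GeneRecord]:
        return [r for r in self.records if r.is_cr()]

    def names(self) -> List[str]:
        return [r.name for r in self.records]

    def extract_seq(self, record: GeneRecord) -> Optional[str]:
        """Gene sequence in transcript orientation (DNA alphabet)."""
        if self.genome_seq is None:
            return None
        parts = [
            self.genome_seq[s - 1 : e]
            for s, e in coords.segments(
                record.start, record.end, self.genome_length, record.wraps_origin
            )
        ]
        seq = "".join(parts)
        if record.strand == "N":
            seq = revcomp(seq)
        return seq

    def validate(self) -> List[str]:
        """Check invariants; returns a list of warning strings.

        Hard violations (coordinates out of range, duplicate names) raise;
        soft oddities (non-canonical start codon, length/codon mismatches)
        are returned as warnings, matching how curated tables deviate from
        the rulebook in practice.
        """
        warnings: List[str] = []
        seen: Dict[str, int] = {}
        for rec in self.records:
            coords.check_position(rec.start, self.genome_length)
            coords.check_position(rec.end, self.genome_length)
            if rec.start > rec.end and not rec.wraps_origin:
                raise ValueError(f"{rec.name}: start > end without wraps_origin")
            if not rec.is_cr() and rec.strand not in ("J", "N"):
                raise ValueError(f"{rec.name}: strand must be J or N")
            if rec.category not in CATEGORIES:
                raise ValueError(f"{rec.name}: unknown category {rec.category!r}")
            seen[rec.name] = seen.get(rec.name, 0) + 1
            length = rec.length(self.genome_length)
            if rec.category == "tRNA" and not TRNA_MIN_LEN <= length <= TRNA_MAX_LEN:
                warnings.append(f"{rec.name}: tRNA length {length} outside [{TRNA_MIN_LEN}, {TRNA_MAX_LEN}]")
            if rec.category == "PCG":
                warnings.extend(_check_pcg_codons(rec, length))
        dups = [n for n, c in seen.items() if c > 1]
        if dups:
            raise ValueError(f"duplicate record names: {dups}")
        return warnings


def _check_pcg_codons(rec: GeneRecord, length: int) -> List[str]:
    warnings: List[str] = []
    if rec.start_codon and rec.start_codon not in START_CODONS:
        warnings.append(f"{rec.name}: non-canonical start codon {rec.start_codon}")
    if rec.stop_codon:
        rem = length % 3
        expected = {0: 3, 1: 1, 2: 2}[rem]
        if len(rec.stop_codon) != expected:
            warnings.append(
                f"{rec.name}: length {length} (mod 3 = {rem}) inconsistent with "
                f"stop codon {rec.stop_codon!r}"
            )
    return warnings


# ---------------------------------------------------------------------------
# Feature arithmetic


def adjacent_relations(
    annotation: MitoAnnotation,
) -> List[Tuple[str, str, int, int]]:
    """Overlap/spacer between each consecutive record pair on the circle.

    Returns ``(nameA, nameB, overlap_bp, spacer_bp)`` for every consecutive
    pair in J-strand start order, including the wrap-around last->first pair.
    Exactly one of overlap/spacer can be positive.
    """
    recs = sorted(annotation.records, key=lambda r: (r.start, r.end))
    out = []
    n = len(recs)
    for i, cur in enumerate(recs):
        nxt = recs[(i + 1) % n]
        gap = coords.circular_gap(cur.end, nxt.start, annotation.genome_length)
        overlap = max(0, -gap)
        spacer = max(0, gap)
        out.append((cur.name, nxt.name, overlap, spacer))
    return out


def all_overlapping_pairs(annotation: MitoAnnotation) -> List[Tuple[str, str, int]]:
    """Every unordered record pair with a positive overlap."""
    recs = annotation.records
    out = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            ov = coords.overlap_length(
                recs[i].span(), recs[j].span(), annotation.genome_length
            )
            if ov > 0:
                out.append((recs[i].name, recs[j].name, ov))
    return out


# ---------------------------------------------------------------------------
# Annotation comparison


@dataclass
class GeneChange:
    old_start: int
    old_end: int
    new_start: int
    new_end: int
    boundary_moved: str  # "5prime" | "3prime" | "both" | "none"


@dataclass
class AnnotationDiff:
    """Differences between two annotations of the same genome."""

    per_gene: Dict[str, GeneChange] = field(default_factory=dict)
    eliminated_overlaps: List[Tuple[str, str]] = field(default_factory=list)
    reduced_spacers: List[Tuple[str, str, int, int]] = field(default_factory=list)

    def changed_genes(self) -> List[str]:
        return [n for n, c in self.per_gene.items() if c.boundary_moved != "none"]

    def is_empty(self) -> bool:
        return not self.changed_genes()


def _moved_label(old: GeneRecord, new: GeneRecord) -> str:
    m5 = old.five_prime() != new.five_prime()
    m3 = old.three_prime() != new.three_prime()
    if m5 and m3:
        return "both"
    if m5:
        return "5prime"
    if m3:
        return "3prime"
    return "none"


def compare_annotations(a: MitoAnnotation, b: MitoAnnotation) -> AnnotationDiff:
    """Diff two annotations sharing a genome and gene set."""
    if a.genome_length != b.genome_length:
        raise ReconciliationError(
            f"genome lengths differ: {a.genome_length} vs {b.genome_length}"
        )
    names_a = set(a.names())
    names_b = set(b.names())
    if names_a != names_b:
        only_a = sorted(names_a - names_b)
        only_b = sorted(names_b - names_a)
        raise ReconciliationError(
            f"gene sets differ: only in first={only_a}, only in second={only_b}"
        )
    diff = AnnotationDiff()
    for rec_a in a.records:
        rec_b = b.get(rec_a.name)
        diff.per_gene[rec_a.name] = GeneChange(
            rec_a.start, rec_a.end, rec_b.start, rec_b.end, _moved_label(rec_a, rec_b)
        )
    ov_a = {frozenset((x, y)) for x, y, _ in all_overlapping_pairs(a)}
    ov_b = {frozenset((x, y)) for x, y, _ in all_overlapping_pairs(b)}
    diff.eliminated_overlaps = sorted(
        tuple(sorted(p)) for p in ov_a - ov_b
    )
    spacers_b = {
        frozenset((x, y)): sp for x, y, _, sp in adjacent_relations(b)
    }
    for x, y, ov, sp in adjacent_relations(a):
        key = frozenset((x, y))
        if sp > 0 and key in spacers_b and spacers_b[key] < sp:
            diff.reduced_spacers.append((x, y, sp, spacers_b[key]))
    return diff


# ---------------------------------------------------------------------------
# Transcript-evidence boundary refinement


def _transcript_bio_ends(t, genome_length: int) -> Tuple[int, int]:
    """(5' position, 3' position) of a transcript in genomic coordinates."""
    if t.strand == "N":
        return t.end, t.start
    return t.start, t.end


def _sense_content(annotation: MitoAnnotation, t, threshold: float = 0.5):
    """Same-strand genes covered by > threshold of their length, in
    transcript 5'->3' order; falls back to the best-overlap gene."""
    L = annotation.genome_length
    span = (t.start, t.end, getattr(t, "wraps_origin", False))
    hits = []
    best = None
    best_ov = 0
    for rec in annotation.genes():
        if rec.strand != t.strand:
            continue
        ov = coords.overlap_length(span, rec.span(), L)
        if ov > best_ov:
            best, best_ov = rec, ov
        if ov > threshold * rec.length(L):
            hits.append(rec)
    if not hits and best is not None:
        hits = [best]
    t5, _ = _transcript_bio_ends(t, L)
    t_len = coords.span_length(span[0], span[1], L, span[2])

    def _entry(r) -> Tuple[int, int]:
        # offset along the transcript of the gene's first covered base; a
        # gene starting upstream of the transcript 5' end enters at 0 (its
        # raw modular offset would wrap to ~L)
        if t.strand == "J":
            off, off_exit = (r.five_prime() - t5) % L, (r.three_prime() - t5) % L
        else:
            off, off_exit = (t5 - r.five_prime()) % L, (t5 - r.three_prime()) % L
        if off >= t_len:
            off = 0
        return off, off_exit

    hits.sort(key=_entry)
    return hits


def _cluster_positions(positions: Sequence[int], tol: int, genome_length: int):
    """Greedy pileup clustering: repeatedly take the modal exact position and
    absorb everything within +-tol.  Returns (position, support) pairs."""
    counts: Dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    clusters = []
    while counts:
        pos = max(counts, key=lambda p: (counts[p], -p))
        members = [
            p for p in counts if coords.circular_distance(p, pos, genome_length) <= tol
        ]
        support = sum(counts[p] for p in members)
        clusters.append((pos, support))
        for p in members:
            del counts[p]
    return clusters


def _codon_fields(annotation: MitoAnnotation, rec: GeneRecord) -> Tuple[Optional[str], Optional[str]]:
    seq = annotation.extract_seq(rec)
    if seq is None or len(seq) < 4:
        return None, None
    rna = as_rna(seq)
    start = rna[:3]
    rem = len(rna) % 3
    stop = rna[-3:] if rem == 0 else rna[-rem:]
    return start, stop


def _pcg_move_valid(annotation: MitoAnnotation, rec: GeneRecord) -> bool:
    """A moved PCG must keep a valid start and a complete-or-truncated stop."""
    start, stop = _codon_fields(annotation, rec)
    if start is None:
        return True  # no sequence: only length checks apply
    if start not in START_CODONS and start != rec.start_codon:
        return False
    rem = rec.length(annotation.genome_length) % 3
    if rem == 0:
        return stop in COMPLETE_STOPS
    if rem == 1:
        return stop == "U"
    return stop == "UA"


def refine_boundaries(
    annotation: MitoAnnotation,
    transcripts: Iterable,
    tol: int = 3,
    min_support: int = 5,
) -> Tuple[MitoAnnotation, AnnotationDiff]:
    """Move gene boundaries to transcript-end pileups.

    For each gene terminus, transcript ends of same-strand transcripts whose
    terminal content gene is that gene are clustered; if the winning pileup
    has at least ``min_support`` members its position becomes the new
    boundary, provided the result keeps the gene's category invariants (tRNA
    length window; for PCGs with a genome sequence, a valid start codon and a
    complete or truncated stop).  Degradation scatter is filtered by the
    pileup support requirement itself.  The operation is idempotent.
    """
    transcripts = list(transcripts)
    L = annotation.genome_length
    if tol < 0:
        raise ValueError("tol must be >= 0")
    old = MitoAnnotation(
        L, [replace(r) for r in annotation.records], annotation.genome_seq
    )
    if not transcripts:
        diff = compare_annotations(old, old)
        return old, diff

    evidence: Dict[Tuple[str, str], List[int]] = {}
    for t in transcripts:
        if t.strand not in ("J", "N"):
            continue
        content = _sense_content(annotation, t)
        if not content:
            continue
        t5, t3 = _transcript_bio_ends(t, L)
        evidence.setdefault((content[0].name, "5"), []).append(t5)
        evidence.setdefault((content[-1].name, "3"), []).append(t3)

    new_records: List[GeneRecord] = []
    for rec in annotation.records:
        if rec.is_cr():
            new_records.append(replace(rec))
            continue
        cand: Dict[str, Optional[int]] = {"5": None, "3": None}
        for side in ("5", "3"):
            current = rec.five_prime() if side == "5" else rec.three_prime()
            pos_list = evidence.get((rec.name, side), [])
            clusters = _cluster_positions(pos_list, tol, L)
            clusters = [c for c in clusters if c[1] >= min_support]
            if not clusters:
                continue
            clusters.sort(
                key=lambda c: (
                    -c[1],
                    coords.circular_distance(c[0], current, L),
                    c[0],
                )
            )
            winner = clusters[0][0]
            if winner != current:
                cand[side] = winner
        new_rec = _apply_move(annotation, rec, cand["5"], cand["3"])
        new_records.append(new_rec)

    refined = MitoAnnotation(L, new_records, annotation.genome_seq)
    diff = compare_annotations(old, refined)
    return refined, diff


def _apply_move(
    annotation: MitoAnnotation,
    rec: GeneRecord,
    new5: Optional[int],
    new3: Optional[int],
) -> GeneRecord:
    """Try boundary candidates, keeping the first combination that validates."""
    L = annotation.genome_length
    combos = [(new5, new3)]
    if new5 is not None and new3 is not None:
        combos += [(new5, None), (None, new3)]
    for c5, c3 in combos:
        if c5 is None and c3 is None:
            continue
        p5 = c5 if c5 is not None else rec.five_prime()
        p3 = c3 if c3 is not None else rec.three_prime()
        if rec.strand == "N":
            start, end = p3, p5
        else:
            start, end = p5, p3
        wraps = start > end
        trial = replace(rec, start=start, end=end, wraps_origin=wraps)
        length = trial.length(L)
        if length < 1 or length > L:
            continue
        if rec.category == "tRNA" and not TRNA_MIN_LEN <= length <= TRNA_MAX_LEN:
            continue
        if rec.category == "PCG" and not _pcg_move_valid(annotation, trial):
            continue
        if rec.category == "PCG" and annotation.genome_seq is not None:
            start_c, stop_c = _codon_fields(annotation, trial)
            trial = replace(trial, start_codon=start_c, stop_codon=stop_c)
        logger.info(
            "refined %s: %d-%d -> %d-%d", rec.name, rec.start, rec.end, start, end
        )
        return trial
    return replace(rec)
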