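"""Isoform calling by 5'/3' end clustering, and degradation orientation.

An isoform is a reproducible transcript species of one gene or unit defined
by identical (up to sequencing end noise) 5' and 3' ends; transcripts that
match no cluster at one or both ends are exonucleolytic degradation
candidates, and the end at which they vary reveals the degradation
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from . import coords
from .transcripts import TranscriptAlignment


@dataclass
class IsoformCluster:
    unit: str
    end5: int
    end3: int
    support: int

    def length(self, genome_length: int) -> int:
        lo, hi = (self.end5, self.end3)
        if lo > hi:
            lo, hi = hi, lo
        return coords.span_length(lo, hi, genome_length)


@dataclass
class DegradationProfile:
    unit: str
    orientation: str  # five_to_three | three_to_five | both | none
    n_truncated: int
    end5_spread: int
    end3_spread: int


def cluster_isoforms(
    transcripts: Sequence[TranscriptAlignment],
    tol: int = 3,
    min_support: int = 5,
    unit: str = "",
    genome_length: int = 0,
) -> Tuple[List[IsoformCluster], List[TranscriptAlignment]]:
    """Greedy end-pair clustering.

    Repeatedly takes the modal exact ``(end5, end3)`` pair (ties broken by
    the smaller coordinates), absorbs every transcript within ``tol`` at
    *both* ends, and emits a cluster if its support reaches ``min_support``.
    Returns ``(clusters, degradation_candidates)``.  Deterministic in the
    input order.
    """
    if genome_length <= 0:
        genome_length = max(max(t.start, t.end) for t in transcripts) if transcripts else 1
    remaining: Dict[Tuple[int, int], List[TranscriptAlignment]] = {}
    for t in transcripts:
        remaining.setdefault(t.bio_ends(), []).append(t)
    clusters: List[IsoformCluster] = []
    leftovers: List[TranscriptAlignment] = []
    while remaining:
        modal = max(remaining, key=lambda p: (len(remaining[p]), -p[0], -p[1]))
        members = [
            p
            for p in remaining
            if coords.circular_distance(p[0], modal[0], genome_length) <= tol
            and coords.circular_distance(p[1], modal[1], genome_length) <= tol
        ]
        support = sum(len(remaining[p]) for p in members)
        if support < min_support:
            break
        clusters.append(IsoformCluster(unit, modal[0], modal[1], support))
        for p in members:
            del remaining[p]
    for ts in remaining.values():
        leftovers.extend(ts)
    clusters.sort(key=lambda c: (-c.support, c.end5, c.end3))
    return clusters, leftovers


def degradation_orientation(
    unit_transcripts: Sequence[TranscriptAlignment],
    clusters: Sequence[IsoformCluster],
    tol: int = 3,
    unit: str = "",
    genome_length: int = 0,
) -> DegradationProfile:
    """Infer which end(s) exonucleolytic degradation attacks.

    Truncated transcripts (cluster members excluded) whose 3' end still
    matches a cluster but whose 5' end varies indicate 5'->3' degradation;
    the converse indicates 3'->5'; variation at both ends indicates both.
    """
    if genome_length <= 0:
        genome_length = (
            max(max(t.start, t.end) for t in unit_transcripts) if unit_transcripts else 1
        )
    ends5 = [c.end5 for c in clusters]
    ends3 = [c.end3 for c in clusters]

    def _matches(pos: int, refs: List[int]) -> bool:
        return any(coords.circular_distance(pos, r, genome_length) <= tol for r in refs)

    truncated: List[TranscriptAlignment] = []
    var5 = var3 = 0
    t5s: List[int] = []
    t3s: List[int] = []
    for t in unit_transcripts:
        t5, t3 = t.bio_ends()
        m5 = _matches(t5, ends5)
        m3 = _matches(t3, ends3)
        if m5 and m3:
            continue  # isoform member
        truncated.append(t)
        if not m5:
            var5 += 1
            t5s.append(t5)
        if not m3:
            var3 += 1
            t3s.append(t3)
    if not truncated:
        orientation = "none"
    elif var5 and var3:
        orientation = "both"
    elif var5:
        orientation = "five_to_three"
    else:
        orientation = "three_to_five"
    spread5 = max(t5s) - min(t5s) if t5s else 0
    spread3 = max(t3s) - min(t3s) if t3s else 0
    return DegradationProfile(unit, orientation, len(truncated), spread5, spread3)


def isoform_table(clusters: Iterable[IsoformCluster], genome_length: int) -> pd.DataFrame:
    rows = [
        {
            "unit": c.unit,
            "end5": c.end5,
            "end3": c.end3,
            "support": c.support,
            "length": c.length(genome_length),
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["unit", "end5", "end3", "support", "length"])
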