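"""Strand-specific per-base coverage (the quantitative transcription map)
and relative gene-expression ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import coords
from .annotation import MitoAnnotation
from .transcripts import TranscriptAlignment


@dataclass
class CoverageTrack:
    """Per-base read depth of one strand; index = position - 1."""

    strand: str
    depth: np.ndarray

    @property
    def genome_length(self) -> int:
        return len(self.depth)

    def total(self) -> int:
        return int(self.depth.sum())

    def mean_over(self, start: int, end: int, wraps: bool = False) -> float:
        segs = coords.segments(start, end, self.genome_length, wraps)
        vals = np.concatenate([self.depth[s - 1 : e] for s, e in segs])
        return float(vals.mean())

    def min_over(self, start: int, end: int, wraps: bool = False) -> int:
        segs = coords.segments(start, end, self.genome_length, wraps)
        return int(min(self.depth[s - 1 : e].min() for s, e in segs))


def compute_coverage(
    transcripts: Iterable[TranscriptAlignment], genome_length: int
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Per-base depth on each strand; every transcript increments every
    position it covers (wrapping the origin where flagged)."""
    tracks = {
        "J": np.zeros(genome_length, dtype=np.int64),
        "N": np.zeros(genome_length, dtype=np.int64),
    }
    for t in transcripts:
        t.validate(genome_length)
        arr = tracks[t.strand]
        for s, e in coords.segments(t.start, t.end, genome_length, t.wraps_origin):
            arr[s - 1 : e] += 1
    return CoverageTrack("J", tracks["J"]), CoverageTrack("N", tracks["N"])


def gene_expression_ranking(
    coverage: Tuple[CoverageTrack, CoverageTrack],
    annotation: MitoAnnotation,
    units: Optional[Sequence[Union[str, Sequence[str]]]] = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Relative expression of genes (or merged gene units), highest first.

    The statistic is the mean per-base depth over the unit's span on its
    coding strand (``statistic="total"`` sums instead).  Ties are broken
    alphabetically and flagged in the ``tied`` column.
    """
    track = {c.strand: c for c in coverage}
    if units is None:
        units = [r.name for r in annotation.records if r.category in ("PCG", "rRNA")]
    rows = []
    for unit in units:
        genes = [unit] if isinstance(unit, str) else list(unit)
        name = "/".join(genes)
        depths: List[float] = []
        total_len = 0
        total_sum = 0.0
        for gname in genes:
            rec = annotation.get(gname)
            glen = rec.length(annotation.genome_length)
            if glen == 0:
                raise ValueError(f"unit {name}: gene {gname} has zero length")
            strand = rec.strand if rec.strand in ("J", "N") else "J"
            mean_d = track[strand].mean_over(rec.start, rec.end, rec.wraps_origin)
            depths.append(mean_d)
            total_len += glen
            total_sum += mean_d * glen
        mean_depth = total_sum / total_len
        value = total_sum if statistic == "total" else mean_depth
        rows.append({"unit": name, "mean_depth": mean_depth, "value": value})
    df = pd.DataFrame(rows).sort_values(["value", "unit"], ascending=[False, True])
    df["rank"] = range(1, len(df) + 1)
    df["tied"] = df.duplicated("value", keep=False)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# bedGraph I/O (0-based half-open, as the format specifies)


def write_bedgraph(track: CoverageTrack, path, chrom: str = "ChrM") -> None:
    d = track.depth
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}_{track.strand}"\n')
        if len(d) == 0:
            return
        run_start = 0
        for i in range(1, len(d) + 1):
            if i == len(d) or d[i] != d[run_start]:
                fh.write(f"{chrom}\t{run_start}\t{i}\t{int(d[run_start])}\n")
                run_start = i


def read_bedgraph(path, genome_length: int, strand: str) -> CoverageTrack:
    depth = np.zeros(genome_length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            _chrom, s, e, v = line.split()
            depth[int(s) : int(e)] = int(v)
    return CoverageTrack(strand, depth)
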