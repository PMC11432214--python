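"""Forward simulator of mitochondrial transcription and RNA processing.

Molecules are born at strand-specific transcription initiation sites
(chosen proportionally to strength), elongate along their strand, terminate
stochastically at termination sites (read-through allowed, hard stop after
one full circle), are processed by tRNA-punctuated cleavage running either
3'->5' (reverse) or 5'->3' (forward) with per-junction completion, may be
exonucleolytically degraded from one end (geometric trim length), receive a
polyA tail length and integer-rounded Gaussian end noise.  Every emitted
transcript carries a ground-truth record so each pipeline stage can be
scored against what actually happened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import coords
from .annotation import GeneRecord, MitoAnnotation
from .classify import MATURE_MULTI_UNITS
from .transcripts import TranscriptAlignment

logger = logging.getLogger(__name__)


class ScenarioError(ValueError):
    """The simulation scenario is internally inconsistent."""


@dataclass
class SimScenario:
    """Study conditions for one simulation run."""

    annotation: MitoAnnotation
    tis: Dict[str, List[Tuple[int, float]]]  # strand -> [(position, strength)]
    tts: Dict[str, List[Tuple[int, float]]]  # strand -> [(position, read_through)]
    cleavage_completion: float = 0.9
    reverse_fraction: float = 0.9
    degradation_fraction: float = 0.2
    degradation_mean_trim: float = 150.0
    degradation_p_five_prime: float = 0.5
    polya_mean: float = 30.0
    polya_sd: float = 10.0
    end_noise_sd: float = 1.0
    n_transcripts: int = 5000
    min_length: int = 20
    seed: int = 42
    name: str = "scenario"

    def validate(self) -> None:
        L = self.annotation.genome_length
        for prob, label in (
            (self.cleavage_completion, "cleavage completion"),
            (self.reverse_fraction, "reverse fraction"),
            (self.degradation_fraction, "degradation fraction"),
            (self.degradation_p_five_prime, "degradation 5' probability"),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ScenarioError(f"{label} must be in [0, 1], got {prob}")
        total = 0.0
        for strand, sites in self.tis.items():
            strength = sum(w for _, w in sites)
            if any(w < 0 for _, w in sites):
                raise ScenarioError(f"negative TIS strength on strand {strand}")
            if strength > 0 and not sites:
                raise ScenarioError(f"no active TIS on strand {strand}")
            for pos, _ in sites:
                coords.check_position(pos, L)
            total += strength
        if total <= 0:
            raise ScenarioError("no active TIS on any strand")
        for strand, sites in self.tts.items():
            for pos, rt in sites:
                coords.check_position(pos, L)
                if not 0.0 <= rt <= 1.0:
                    raise ScenarioError(f"TTS read-through must be in [0, 1], got {rt}")

    @classmethod
    def from_yaml(cls, path, annotation: Optional[MitoAnnotation] = None) -> "SimScenario":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg, annotation)

    @classmethod
    def from_dict(cls, cfg: dict, annotation: Optional[MitoAnnotation] = None) -> "SimScenario":
        if annotation is None:
            ann_name = cfg.get("annotation", "sericothrips_refined")
            from .fixtures import sericothrips_annotation

            if ann_name in ("sericothrips_refined", "sericothrips_dna"):
                annotation = sericothrips_annotation(refined=ann_name.endswith("refined"))
            else:
                raise ScenarioError(f"unknown annotation fixture {ann_name!r}")
        tis = {
            strand: [(int(s["position"]), float(s["strength"])) for s in sites]
            for strand, sites in cfg.get("tis", {}).items()
        }
        tts = {
            strand: [(int(s["position"]), float(s["read_through"])) for s in sites]
            for strand, sites in cfg.get("tts", {}).items()
        }
        cleav = cfg.get("cleavage", {})
        degr = cfg.get("degradation", {})
        polya = cfg.get("polya", {})
        sc = cls(
            annotation=annotation,
            tis=tis,
            tts=tts,
            cleavage_completion=float(cleav.get("completion", 0.9)),
            reverse_fraction=float(cleav.get("reverse_fraction", 0.9)),
            degradation_fraction=float(degr.get("fraction", 0.2)),
            degradation_mean_trim=float(degr.get("mean_trim", 150.0)),
            degradation_p_five_prime=float(degr.get("p_five_prime", 0.5)),
            polya_mean=float(polya.get("mean", 30.0)),
            polya_sd=float(polya.get("sd", 10.0)),
            end_noise_sd=float(cfg.get("end_noise_sd", 1.0)),
            n_transcripts=int(cfg.get("n_transcripts", 5000)),
            min_length=int(cfg.get("min_length", 20)),
            seed=int(cfg.get("seed", 42)),
            name=str(cfg.get("name", "scenario")),
        )
        sc.validate()
        return sc


def default_scenario(annotation: Optional[MitoAnnotation] = None, **overrides) -> SimScenario:
    """The bundled Sericothrips-like scenario, optionally overridden."""
    from .fixtures import default_scenario_path

    sc = SimScenario.from_yaml(default_scenario_path(), annotation)
    for key, value in overrides.items():
        if not hasattr(sc, key):
            raise TypeError(f"unknown scenario field {key!r}")
        setattr(sc, key, value)
    sc.validate()
    return sc


@dataclass
class TruthRecord:
    """What actually happened to one emitted molecule."""

    id: str
    label: str
    content: List[str]
    end5: int  # pre-noise biological 5' genomic position
    end3: int
    degraded_end: Optional[str] = None  # 5prime | 3prime
    trim_len: int = 0
    tis: Optional[int] = None
    tts: Optional[int] = None


@dataclass
class SimResult:
    transcripts: List[TranscriptAlignment]
    truths: List[TruthRecord]
    n_dropped_short: int = 0


# ---------------------------------------------------------------------------


def _junction_gaps(annotation: MitoAnnotation, strand: str) -> List[int]:
    """Cleavable breakpoints: gap ``g`` sits between positions g and g+1
    (gap L wraps to position 1); a same-strand tRNA contributes the gaps at
    both its boundaries."""
    L = annotation.genome_length
    gaps = set()
    for rec in annotation.genes():
        if rec.category != "tRNA" or rec.strand != strand:
            continue
        gaps.add(rec.start - 1 if rec.start > 1 else L)
        gaps.add(rec.end)
    return sorted(gaps)


def _gap_offset(gap: int, p5: int, strand: str, L: int) -> int:
    """Offset along the transcript of the breakpoint after transcript
    position ``offset`` (cut separates offsets <= off from > off)."""
    if strand == "J":
        return (gap - p5) % L
    return (p5 - (gap + 1)) % L + 0  # N: cut crossed moving from gap+1 to gap


def _pos_at(p5: int, off: int, strand: str, L: int) -> int:
    if strand == "J":
        return coords.wrap_position(p5 + off, L)
    return coords.wrap_position(p5 - off, L)


class _Simulator:
    def __init__(self, scenario: SimScenario, rng: np.random.Generator):
        self.sc = scenario
        self.rng = rng
        self.L = scenario.annotation.genome_length
        self.ann = scenario.annotation
        self.junctions = {s: _junction_gaps(self.ann, s) for s in ("J", "N")}
        self.strand_weights = {
            s: sum(w for _, w in scenario.tis.get(s, [])) for s in ("J", "N")
        }
        self.genes = self.ann.genes()
        self.gene_len = {g.name: g.length(self.L) for g in self.genes}
        self.crs = self.ann.crs()

    # -- transcription ------------------------------------------------------

    def _draw_primary(self) -> Tuple[str, int, int, int]:
        """Returns (strand, tis, span_length, tts or None)."""
        weights = np.array([self.strand_weights["J"], self.strand_weights["N"]])
        strand = ("J", "N")[self.rng.choice(2, p=weights / weights.sum())]
        sites = self.sc.tis[strand]
        ws = np.array([w for _, w in sites], dtype=float)
        tis = sites[self.rng.choice(len(sites), p=ws / ws.sum())][0]
        # termination sites in encounter order
        tts_list = []
        for pos, rt in self.sc.tts.get(strand, []):
            if strand == "J":
                d = (pos - tis) % self.L
            else:
                d = (tis - pos) % self.L
            if d > 0:
                tts_list.append((d, pos, rt))
        tts_list.sort()
        for d, pos, rt in tts_list:
            if self.rng.random() >= rt:
                return strand, tis, d + 1, pos
        return strand, tis, self.L, None  # hard stop after one full circle

    # -- cleavage -----------------------------------------------------------

    def _cleave(self, strand: str, p5: int, span_len: int) -> List[Tuple[int, int]]:
        """Offsets-(start, end) fragments after direction-ordered cleavage
        with stalling at the first junction whose completion draw fails."""
        offs = [
            _gap_offset(g, p5, strand, self.L) for g in self.junctions[strand]
        ]
        internal = sorted(o for o in offs if 0 <= o < span_len - 1)
        reverse = self.rng.random() < self.sc.reverse_fraction
        order = list(reversed(internal)) if reverse else list(internal)
        cuts = []
        for off in order:
            if self.rng.random() < self.sc.cleavage_completion:
                cuts.append(off)
            else:
                break  # processing stalls; upstream junctions stay intact
        cuts.sort()
        frags = []
        prev = 0
        for c in cuts:
            frags.append((prev, c))
            prev = c + 1
        frags.append((prev, span_len - 1))
        return frags

    # -- truth labelling ----------------------------------------------------
    #
    # Class labels are observational: they are defined over the transcript
    # geometry under the study's end-matching tolerance, so a trim that
    # leaves no geometric signature (e.g. confined to a retained UTR, or on
    # a CR/antisense fragment) does not make the molecule "degraded" — the
    # generative facts live in TruthRecord.degraded_end / trim_len instead.

    def _end_ok(self, strand: str, end_pos: int, side: str, terminal, tol: int) -> bool:
        """True when this end carries no truncation signature relative to
        its terminal sense gene (mirrors the class definition, applied to
        exact pre-noise ends)."""
        L = self.L
        boundary = terminal.five_prime() if side == "5" else terminal.three_prime()
        sign = 1 if strand == "J" else -1
        d = (end_pos - boundary) % L if side == "5" else (boundary - end_pos) % L
        if d > L // 2:
            d -= L
        short = d * sign
        if short > tol:
            return False
        overhang = -short
        if overhang > tol:
            step = 1 if strand == "J" else -1
            if side == "5":
                lo, hi = end_pos, coords.wrap_position(boundary - step, L)
            else:
                lo, hi = coords.wrap_position(boundary + step, L), end_pos
            if strand == "N":
                lo, hi = hi, lo
            span = (lo, hi, lo > hi)
            for g in self.genes:
                if g.strand != strand or g.name == terminal.name:
                    continue
                if coords.overlap_length(span, g.span(), L) > tol:
                    return False
        return True

    def _truth(self, strand: str, f5: int, f3: int, tol: int = 3) -> Tuple[str, List[str]]:
        span = self._span_of(strand, f5, f3)
        t_len = coords.span_length(span[0], span[1], self.L, span[2])
        sense: List[Tuple[int, GeneRecord]] = []
        anti: List[Tuple[int, str]] = []
        for g in self.genes:
            ov = coords.overlap_length(span, g.span(), self.L)
            if ov == 0:
                continue
            glen = self.gene_len[g.name]
            p = g.five_prime() if g.strand == strand else g.three_prime()
            q = g.three_prime() if g.strand == strand else g.five_prime()
            if strand == "J":
                off, off_exit = (p - f5) % self.L, (q - f5) % self.L
            else:
                off, off_exit = (f5 - p) % self.L, (f5 - q) % self.L
            if off >= t_len:
                off = 0  # gene begins upstream of the transcript 5' end
            if g.strand == strand and ov > 0.5 * glen:
                sense.append(((off, off_exit), g))
            elif g.strand != strand and (ov == glen or ov > 0.5 * glen):
                anti.append(((off, off_exit), g.name))
        sense.sort(key=lambda item: item[0])
        anti.sort(key=lambda item: item[0])
        content = [g.name for _, g in sense] + [f"as{n}" for _, n in anti]
        if sense:
            names = [g.name for _, g in sense]
            ok5 = self._end_ok(strand, f5, "5", sense[0][1], tol)
            ok3 = self._end_ok(strand, f3, "3", sense[-1][1], tol)
            if not (ok5 and ok3):
                return "degraded", content
            if len(names) == 1:
                return "mature_mono", content
            if frozenset(names) in MATURE_MULTI_UNITS:
                return "mature_multi", content
            return "polycistronic", content
        if anti:
            return "antisense", content
        cr_ov = sum(coords.overlap_length(span, cr.span(), self.L) for cr in self.crs)
        if cr_ov > 0.5 * t_len:
            return "ncRNA_CR", content
        return "degraded", content

    def _span_of(self, strand: str, f5: int, f3: int) -> Tuple[int, int, bool]:
        start, end = (f5, f3) if strand == "J" else (f3, f5)
        return (start, end, start > end)

    # -- one molecule -------------------------------------------------------

    def emit(self, idx: int) -> Tuple[Optional[TranscriptAlignment], Optional[TruthRecord]]:
        sc, rng, L = self.sc, self.rng, self.L
        strand, tis, span_len, tts = self._draw_primary()
        frags = self._cleave(strand, tis, span_len)
        off_a, off_b = frags[rng.integers(len(frags))]

        trim = 0
        degraded_end = None
        frag_len = off_b - off_a + 1
        if sc.degradation_fraction > 0 and rng.random() < sc.degradation_fraction and frag_len > 1:
            trim = int(min(rng.geometric(1.0 / max(sc.degradation_mean_trim, 1.0)), frag_len - 1))
            if rng.random() < sc.degradation_p_five_prime:
                degraded_end = "5prime"
                off_a += trim
            else:
                degraded_end = "3prime"
                off_b -= trim

        f5 = _pos_at(tis, off_a, strand, L)
        f3 = _pos_at(tis, off_b, strand, L)
        label, content = self._truth(strand, f5, f3)
        truth = TruthRecord(
            id=f"sim{idx:06d}",
            label=label,
            content=content,
            end5=f5,
            end3=f3,
            degraded_end=degraded_end,
            trim_len=trim,
            tis=tis if off_a == 0 and trim == 0 else None,
            tts=tts if off_b == span_len - 1 and trim == 0 else None,
        )

        length = off_b - off_a + 1
        if sc.end_noise_sd > 0:
            d5 = int(round(rng.normal(0.0, sc.end_noise_sd)))
            d3 = int(round(rng.normal(0.0, sc.end_noise_sd)))
            # noise must not invert the molecule
            if length - d5 + d3 < 1:
                d5 = d3 = 0
            sign = 1 if strand == "J" else -1
            f5 = coords.wrap_position(f5 + sign * d5, L)
            f3 = coords.wrap_position(f3 + sign * d3, L)
            length = length - d5 + d3
        if length < sc.min_length or length > L:
            return None, None
        polya = max(0, int(round(rng.normal(sc.polya_mean, sc.polya_sd))))
        start, end, wraps = self._span_of(strand, f5, f3)
        t = TranscriptAlignment(
            id=truth.id, strand=strand, start=start, end=end,
            wraps_origin=wraps, polyA_len=polya,
        )
        return t, truth


def simulate_transcripts(
    scenario: SimScenario, rng: Optional[np.random.Generator] = None
) -> SimResult:
    """Run the generative model; deterministic for a fixed scenario seed."""
    scenario.validate()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    sim = _Simulator(scenario, rng)
    transcripts: List[TranscriptAlignment] = []
    truths: List[TruthRecord] = []
    dropped = 0
    for i in range(scenario.n_transcripts):
        t, truth = sim.emit(i)
        if t is None:
            dropped += 1
            continue
        transcripts.append(t)
        truths.append(truth)
    if dropped:
        logger.info("dropped %d transcripts shorter than %d nt", dropped, scenario.min_length)
    return SimResult(transcripts, truths, dropped)


def truth_table(truths: Sequence[TruthRecord]):
    import pandas as pd

    return pd.DataFrame([vars(t) for t in truths])


# ---------------------------------------------------------------------------
# Toy genome generator


_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, n: int, at_rich: bool = False) -> str:
    p = [0.35, 0.15, 0.15, 0.35] if at_rich else None
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_toy_genome(
    n_genes: int = 8,
    seed: int = 0,
    duplicated_cr: bool = False,
    repeat_len: int = 140,
) -> Tuple[MitoAnnotation, str]:
    """A random compact circular annotation plus matching sequence.

    Mixes PCGs (valid AUA/AUU starts, complete UAA stops), tRNAs, one rRNA
    and one control region (two, sharing a planted repeat, when
    ``duplicated_cr``); genes are separated by 0-5 bp spacers and never
    overlap illegally.
    """
    if n_genes < 4:
        raise ValueError("need at least 4 genes")
    rng = np.random.default_rng(seed)
    cats = ["PCG", "tRNA", "rRNA"] + [
        ("tRNA" if rng.random() < 0.6 else "PCG") for _ in range(n_genes - 3)
    ]
    rng.shuffle(cats)
    records: List[GeneRecord] = []
    chunks: List[str] = []
    pos = 1
    counters = {"PCG": 0, "tRNA": 0, "rRNA": 0}
    cr_seqs: List[str] = []
    cr_slots = [len(cats) // 2] + ([len(cats)] if duplicated_cr else [])

    def _add_cr(index: int) -> None:
        nonlocal pos
        length = int(rng.integers(max(200, repeat_len + 40), max(320, repeat_len + 80)))
        if cr_seqs:  # plant the shared repeat from the first CR
            donor = cr_seqs[0]
            off = int(rng.integers(0, len(donor) - repeat_len + 1))
            repeat = donor[off : off + repeat_len]
            pad = length - repeat_len
            seq = _rand_seq(rng, pad // 2, True) + repeat + _rand_seq(rng, pad - pad // 2, True)
        else:
            seq = _rand_seq(rng, length, at_rich=True)
        cr_seqs.append(seq)
        records.append(
            GeneRecord(f"CR{len(cr_seqs)}", "CR", ".", pos, pos + len(seq) - 1)
        )
        chunks.append(seq)
        pos += len(seq)

    for i, cat in enumerate(cats):
        if i in cr_slots:
            _add_cr(i)
        strand = "J" if rng.random() < 0.75 else "N"
        counters[cat] += 1
        name = f"{cat.lower()}{counters[cat]}"
        if cat == "PCG":
            n_codons = int(rng.integers(50, 200))
            body = "".join(
                rng.choice(["GCA", "TTC", "GGA", "CTT", "ATC", "GAA"])
                for _ in range(n_codons)
            )
            seq = str(rng.choice(["ATA", "ATT"])) + body + "TAA"
            start_codon, stop_codon = (seq[:3].replace("T", "U"), "UAA")
        else:
            length = int(rng.integers(55, 71)) if cat == "tRNA" else int(rng.integers(700, 1100))
            seq = _rand_seq(rng, length)
            start_codon = stop_codon = None
        placed = seq if strand == "J" else _revcomp(seq)
        records.append(
            GeneRecord(
                name, cat, strand, pos, pos + len(seq) - 1,
                start_codon=start_codon, stop_codon=stop_codon,
            )
        )
        chunks.append(placed)
        pos += len(seq)
        spacer = int(rng.integers(0, 6))
        if spacer:
            chunks.append(_rand_seq(rng, spacer))
            pos += spacer
    if len(cr_seqs) < (2 if duplicated_cr else 1):
        _add_cr(len(cats))
    genome_seq = "".join(chunks)
    ann = MitoAnnotation(len(genome_seq), records, genome_seq)
    return ann, genome_seq


def _revcomp(seq: str) -> str:
    from .annotation import revcomp

    return revcomp(seq)
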