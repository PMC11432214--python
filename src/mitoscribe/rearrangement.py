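"""Gene-order comparison between circular mitogenomes.

Adjacency here is unordered and strand-agnostic: two genes are adjacent if
they are consecutive on the circle, in either orientation.  Control regions
are not genes — they are excluded from orders and blocks — but they act as
adjacency *barriers*: two genes separated by a CR are not adjacent.  This
is the definition under which a swapped pair (trnD-trnK vs trnK-trnD) or a
block-inverted pair (trnV-lrRNA) counts as conserved while a pair separated
by an inserted control region does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, List, Sequence, Set, Tuple

from .annotation import MitoAnnotation

Adjacency = FrozenSet[str]


class GeneSetMismatch(ValueError):
    pass


@dataclass
class GeneOrder:
    """A signed circular gene order (CRs excluded, kept as barriers)."""

    names: List[str]
    strands: List[str]
    #: slot i broken means genes i and (i+1) % n are NOT adjacent (a CR sits
    #: between them on the molecule)
    broken_slots: Set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.strands):
            raise ValueError("names and strands must be parallel")
        if len(self.names) < 3:
            raise ValueError("a circular gene order needs at least 3 genes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("gene names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def strand_of(self, name: str) -> str:
        return self.strands[self.names.index(name)]

    def adjacencies(self) -> Set[Adjacency]:
        n = len(self.names)
        return {
            frozenset((self.names[i], self.names[(i + 1) % n]))
            for i in range(n)
            if i not in self.broken_slots
        }

    @classmethod
    def from_elements(cls, elements: Sequence[Tuple[str, str]]) -> "GeneOrder":
        """Build from an ordered circular element list that may contain CR
        entries (any name starting with ``CR``); CRs become barriers."""
        names: List[str] = []
        strands: List[str] = []
        broken: Set[int] = set()
        pending_break = False
        leading_break = False
        for name, strand in elements:
            if name.upper().startswith("CR"):
                if not names:
                    leading_break = True
                else:
                    pending_break = True
                continue
            if pending_break:
                broken.add(len(names) - 1)
                pending_break = False
            names.append(name)
            strands.append(strand)
        if (pending_break or leading_break) and names:
            broken.add(len(names) - 1)  # barrier on the wrap-around slot
        return cls(names, strands, broken)

    @classmethod
    def from_annotation(cls, annotation: MitoAnnotation) -> "GeneOrder":
        recs = sorted(annotation.records, key=lambda r: (r.start, r.end))
        return cls.from_elements([(r.name, r.strand) for r in recs])

    @classmethod
    def from_string(cls, text: str) -> "GeneOrder":
        """Parse the one-line format ``name[+/-],name[+/-],...``.

        ``+`` is the J strand, ``-`` the N strand; a bare ``CR`` token (or
        CR1/CR2) marks a control region barrier.
        """
        elements = []
        for token in text.strip().split(","):
            token = token.strip()
            if not token:
                continue
            if token.endswith("+"):
                elements.append((token[:-1], "J"))
            elif token.endswith("-"):
                elements.append((token[:-1], "N"))
            else:
                elements.append((token, "J"))
        return cls.from_elements(elements)

    @classmethod
    def from_file(cls, path) -> "GeneOrder":
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        return cls.from_string(",".join(lines))

    def to_string(self) -> str:
        mark = {"J": "+", "N": "-"}
        parts = []
        n = len(self.names)
        for i in range(n):
            parts.append(f"{self.names[i]}{mark.get(self.strands[i], '+')}")
            if i in self.broken_slots and i != n - 1:
                parts.append("CR")
        if (n - 1) in self.broken_slots:
            parts.append("CR")
        return ",".join(parts)


@dataclass
class AdjacencyBlock:
    """A maximal run of genes whose internal adjacencies are shared."""

    genes: List[str]

    @property
    def n_adjacencies(self) -> int:
        return len(self.genes) - 1 if len(self.genes) else 0

    def __len__(self) -> int:
        return len(self.genes)


def _check_same_gene_set(a: GeneOrder, b: GeneOrder) -> None:
    sa, sb = set(a.names), set(b.names)
    if sa != sb:
        raise GeneSetMismatch(
            f"gene sets differ: only in first={sorted(sa - sb)}, "
            f"only in second={sorted(sb - sa)}"
        )


def shared_adjacency_blocks(a: GeneOrder, b: GeneOrder) -> List[AdjacencyBlock]:
    """Maximal chains of genes adjacent (unordered, strand-agnostic) in both
    circular orders.  A fully conserved circle yields one block of all genes."""
    _check_same_gene_set(a, b)
    shared = a.adjacencies() & b.adjacencies()
    n = len(a)
    alive = [
        i not in a.broken_slots
        and frozenset((a.names[i], a.names[(i + 1) % n])) in shared
        for i in range(n)
    ]
    if all(alive):
        return [AdjacencyBlock(list(a.names))]
    blocks: List[AdjacencyBlock] = []
    for start in range(n):
        if alive[start] and not alive[(start - 1) % n]:
            genes = [a.names[start]]
            i = start
            while alive[i]:
                i = (i + 1) % n
                genes.append(a.names[i])
            blocks.append(AdjacencyBlock(genes))
    return blocks


def strand_flips(a: GeneOrder, b: GeneOrder) -> List[str]:
    """Genes encoded on different strands in the two orders."""
    _check_same_gene_set(a, b)
    return sorted(name for name in a.names if a.strand_of(name) != b.strand_of(name))


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (circular, unordered)."""
    _check_same_gene_set(a, b)
    return len(a.adjacencies() - b.adjacencies())
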