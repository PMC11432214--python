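"""Readers and writers for annotations: Table-style TSV, GFF3, FASTA.

The TSV dialect mirrors published mitogenome tables: columns
``gene, category, strand, start, end, start_codon, stop_codon``, 1-based
closed coordinates, N-strand genes printed high-low.  GFF3 output is a
single circular region (``Is_circular=true``); features that wrap the
origin are written with ``end > region length``, the convention GFF3
borrows for circular molecules.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneRecord, MitoAnnotation

logger = logging.getLogger(__name__)

#: second occurrences of these names in published tables are identity slips
_DUP_RENAMES = {"trnL2": "trnL1", "trnS1": "trnS2"}

_GFF_TYPES = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D_loop"}
_GFF_TYPES_INV = {v: k for k, v in _GFF_TYPES.items()}


def read_table_tsv(
    path,
    genome_length: int,
    genome_seq: Optional[str] = None,
    correct_identities: bool = True,
) -> MitoAnnotation:
    """Load an annotation from the table dialect.

    N-strand rows with ``start > end`` are interpreted as printed high-low
    and swapped.  When ``correct_identities`` is set, a duplicated tRNA name
    whose second occurrence is a known identity slip (trnL2 -> trnL1,
    trnS1 -> trnS2) is renamed with a logged warning.
    """
    records: List[GeneRecord] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name = row["gene"].strip()
            strand = (row.get("strand") or "").strip() or "."
            start = int(row["start"])
            end = int(row["end"])
            wraps = False
            if start > end:
                if strand == "N":
                    start, end = end, start  # printed high-low
                else:
                    wraps = True
            if correct_identities and name in seen and name in _DUP_RENAMES:
                new_name = _DUP_RENAMES[name]
                logger.warning(
                    "tRNA identity correction: second %s (%d-%d) renamed %s",
                    name, start, end, new_name,
                )
                name = new_name
            seen[name] = seen.get(name, 0) + 1
            records.append(
                GeneRecord(
                    name=name,
                    category=row["category"].strip(),
                    strand=strand,
                    start=start,
                    end=end,
                    start_codon=(row.get("start_codon") or "").strip() or None,
                    stop_codon=(row.get("stop_codon") or "").strip() or None,
                    wraps_origin=wraps,
                )
            )
    return MitoAnnotation(genome_length, records, genome_seq)


def write_table_tsv(annotation: MitoAnnotation, path) -> None:
    """Write the table dialect; N-strand genes are printed high-low."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "category", "strand", "start", "end", "start_codon", "stop_codon"])
        for r in annotation.records:
            start, end = r.start, r.end
            if r.strand == "N":
                start, end = end, start
            w.writerow(
                [
                    r.name,
                    r.category,
                    "" if r.is_cr() else r.strand,
                    start,
                    end,
                    r.start_codon or "",
                    r.stop_codon or "",
                ]
            )


def write_gff3(annotation: MitoAnnotation, path, seqid: str = "ChrM") -> None:
    L = annotation.genome_length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {L}\n")
        fh.write(
            f"{seqid}\tmitoscribe\tregion\t1\t{L}\t.\t+\t.\t"
            f"ID=region:{seqid};Is_circular=true\n"
        )
        for r in annotation.records:
            end = r.end + L if r.wraps_origin else r.end
            strand = {"J": "+", "N": "-"}.get(r.strand, ".")
            attrs = f"ID={r.name};Name={r.name};category={r.category}"
            if r.start_codon:
                attrs += f";start_codon={r.start_codon}"
            if r.stop_codon:
                attrs += f";stop_codon={r.stop_codon}"
            fh.write(
                f"{seqid}\tmitoscribe\t{_GFF_TYPES[r.category]}\t{r.start}\t{end}"
                f"\t.\t{strand}\t.\t{attrs}\n"
            )


def read_gff3(path, genome_seq: Optional[str] = None) -> MitoAnnotation:
    """Read a single-region circular GFF3 produced by this package (or any
    file using gene/tRNA/rRNA/D_loop feature types on one sequence)."""
    genome_length = None
    records: List[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                genome_length = int(line.split()[-1])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            _seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "region":
                genome_length = int(end)
                continue
            if ftype not in _GFF_TYPES_INV:
                continue
            if genome_length is None:
                raise ValueError("GFF3 lacks a region/sequence-region line")
            s, e = int(start), int(end)
            wraps = e > genome_length
            if wraps:
                e -= genome_length
            category = attr.get("category") or _GFF_TYPES_INV[ftype]
            records.append(
                GeneRecord(
                    name=attr.get("Name") or attr.get("ID") or ftype,
                    category=category,
                    strand={"+": "J", "-": "N"}.get(strand, "."),
                    start=s,
                    end=e,
                    start_codon=attr.get("start_codon"),
                    stop_codon=attr.get("stop_codon"),
                    wraps_origin=wraps,
                )
            )
    if genome_length is None:
        raise ValueError("GFF3 lacks a region/sequence-region line")
    return MitoAnnotation(genome_length, records, genome_seq)


def read_fasta(path) -> str:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_fasta(seq: str, path, name: str = "ChrM") -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def load_annotation(path, genome_seq: Optional[str] = None, genome_length: Optional[int] = None) -> MitoAnnotation:
    """Dispatch on extension: .gff/.gff3 -> GFF3, otherwise the TSV dialect
    (which needs ``genome_length``)."""
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return read_gff3(p, genome_seq)
    if genome_length is None:
        raise ValueError("genome_length is required for table TSV annotations")
    return read_table_tsv(p, genome_length, genome_seq)
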