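"""Bundled reference data: the S. houjii annotation tables transcribed from
the published comparison of DNA-based vs transcript-based annotations, and
the putative ancestral insect gene order.

Known quirks of the published table are preserved verbatim and corrected at
load time with logged warnings:

* the second occurrences of trnL2 (9347-9410) and trnS1 (14,903-14,965) are
  identity slips for trnL1 and trnS2 and are renamed;
* ATP8 is marked N-strand in the table although the text places only ND4,
  ND4L, ND5, trnY, trnP and trnH on the N strand; the loader sets ATP8 to J;
* the refined trnT (9411-9477) spans 67 positions although the printed
  length column says 66; coordinates are stored verbatim.
"""

from __future__ import annotations

import logging
from importlib.resources import files
from typing import Optional

from .annotation import MitoAnnotation
from .annotation_io import read_table_tsv
from .rearrangement import GeneOrder

logger = logging.getLogger(__name__)

SERICOTHRIPS_GENOME_LENGTH = 14_965


def _data_path(name: str):
    return files("mitoscribe").joinpath("data", name)


def sericothrips_annotation(
    refined: bool = True, genome_seq: Optional[str] = None
) -> MitoAnnotation:
    """The S. houjii mitogenome annotation (refined by default, or the
    original DNA-sequencing-based one)."""
    fname = "sericothrips_refined.tsv" if refined else "sericothrips_dna.tsv"
    ann = read_table_tsv(
        _data_path(fname), SERICOTHRIPS_GENOME_LENGTH, genome_seq=genome_seq
    )
    atp8 = ann.get("ATP8")
    if atp8.strand == "N":
        logger.warning(
            "ATP8 strand override: table says N, text places it on J; using J"
        )
        atp8.strand = "J"
    return ann


def ancestral_insect_order() -> GeneOrder:
    """The putative ancestral insect mitochondrial gene order."""
    return GeneOrder.from_file(_data_path("ancestral_insect_order.txt"))


def sericothrips_order() -> GeneOrder:
    return GeneOrder.from_annotation(sericothrips_annotation())


def default_scenario_path():
    return _data_path("shoujii_like.yaml")
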