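"""End-to-end pipeline: simulate (or load) transcripts, refine the
annotation, classify, quantify, cluster isoforms, infer regulatory sites
and compare gene orders — writing one artefact per stage plus a JSON
report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

from . import classify as _classify
from . import coverage as _coverage
from . import isoforms as _isoforms
from . import regulatory as _regulatory
from .annotation import MitoAnnotation, compare_annotations, refine_boundaries
from .annotation_io import write_table_tsv
from .classify import MATURE_MULTI_UNITS, classify_all, classification_table, tally_polycistron_types
from .fixtures import ancestral_insect_order, sericothrips_annotation
from .rearrangement import GeneOrder, breakpoint_distance, shared_adjacency_blocks, strand_flips
from .simulate import SimScenario, default_scenario, simulate_transcripts
from .transcripts import TranscriptAlignment, load_transcripts, write_transcript_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed in a way the inputs explain."""


class PipelineDependencyError(PipelineError):
    """An enabled stage needs the output of a disabled one."""


@dataclass
class PipelineConfig:
    outdir: Path
    scenario_path: Optional[Path] = None  # None -> bundled default scenario
    transcripts_path: Optional[Path] = None  # skip simulation, load instead
    seed: Optional[int] = None
    tol: int = 3
    min_support: int = 5
    min_site_support: int = 3
    refine: bool = True
    classify: bool = True
    coverage: bool = True
    isoforms: bool = True
    regulatory: bool = True
    rearrange: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.scenario_path is not None and self.transcripts_path is not None:
            raise PipelineError("give either a scenario or a transcript file, not both")
        if self.tol < 0 or self.min_support < 1 or self.min_site_support < 1:
            raise PipelineError("tol must be >= 0 and support thresholds >= 1")
        if self.isoforms and not self.classify:
            raise PipelineDependencyError("isoforms stage needs the classify stage")
        if self.regulatory and not self.classify:
            raise PipelineDependencyError("regulatory stage needs the classify stage")


def _isoform_units(annotation: MitoAnnotation) -> List[List[str]]:
    """PCGs and rRNAs, with recognized bicistronic partners merged."""
    names = {r.name for r in annotation.records if r.category in ("PCG", "rRNA")}
    units: List[List[str]] = []
    used: set = set()
    for unit in MATURE_MULTI_UNITS:
        if unit <= names:
            members = sorted(unit)
            units.append(members)
            used |= unit
    units.extend([n] for n in sorted(names - used))
    return units


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the report dictionary."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # --- input transcripts -------------------------------------------------
    annotation = sericothrips_annotation(refined=True)
    if config.transcripts_path is not None:
        transcripts = load_transcripts(config.transcripts_path, annotation.genome_length)
        if not transcripts:
            raise PipelineError(f"no transcripts in {config.transcripts_path}")
        report["input"] = {"source": str(config.transcripts_path)}
    else:
        if config.scenario_path is not None:
            scenario = SimScenario.from_yaml(config.scenario_path)
        else:
            scenario = default_scenario()
        if config.seed is not None:
            scenario.seed = config.seed
        sim = simulate_transcripts(scenario)
        transcripts = sim.transcripts
        write_transcript_tsv(transcripts, out / "transcripts.tsv")
        report["input"] = {
            "source": "simulation",
            "scenario": scenario.name,
            "seed": scenario.seed,
            "n_transcripts": len(transcripts),
            "n_dropped_short": sim.n_dropped_short,
        }
    L = annotation.genome_length

    # --- boundary refinement ----------------------------------------------
    if config.refine:
        dna_annotation = sericothrips_annotation(refined=False)
        refined, diff = refine_boundaries(
            dna_annotation, transcripts, tol=config.tol, min_support=config.min_support
        )
        write_table_tsv(refined, out / "refined_annotation.tsv")
        report["refinement"] = {
            "changed_genes": diff.changed_genes(),
            "eliminated_overlaps": [list(p) for p in diff.eliminated_overlaps],
        }

    # --- classification ----------------------------------------------------
    if config.classify:
        classified = classify_all(transcripts, annotation, tol=config.tol)
        classification_table(classified).to_csv(out / "classification.tsv", sep="\t", index=False)
        labels: dict = {}
        for c in classified:
            labels[c.label] = labels.get(c.label, 0) + 1
        strand_counts = {"J": 0, "N": 0}
        for t in transcripts:
            strand_counts[t.strand] += 1
        poly = tally_polycistron_types(classified)
        poly.to_csv(out / "polycistron_types.tsv", sep="\t", index=False)
        cleavage = _classify.cleavage_direction_evidence(classified, annotation, tol=config.tol)
        rev = sum(e.direction_votes["reverse"] for e in cleavage)
        fwd = sum(e.direction_votes["forward"] for e in cleavage)
        report["classification"] = {
            "labels": labels,
            "strand_counts": strand_counts,
            "n_polycistron_types": int(len(poly)),
            "cleavage_votes": {"reverse": rev, "forward": fwd},
        }

    # --- coverage and expression -------------------------------------------
    if config.coverage:
        cov = _coverage.compute_coverage(transcripts, L)
        _coverage.write_bedgraph(cov[0], out / "coverage_J.bedgraph")
        _coverage.write_bedgraph(cov[1], out / "coverage_N.bedgraph")
        ranking = _coverage.gene_expression_ranking(cov, annotation)
        ranking.to_csv(out / "expression_ranking.tsv", sep="\t", index=False)
        report["coverage"] = {
            "total_bases": cov[0].total() + cov[1].total(),
            "mean_depth": (cov[0].total() + cov[1].total()) / L,
            "top_units": ranking["unit"].head(5).tolist(),
        }

    # --- isoforms -----------------------------------------------------------
    if config.isoforms:
        iso_rows = []
        degr = []
        for unit in _isoform_units(annotation):
            members = _classify.transcripts_of_unit(classified, unit)
            ts = [c.transcript for c in members]
            if not ts:
                continue
            clusters, _left = _isoforms.cluster_isoforms(
                ts, tol=config.tol, min_support=config.min_support,
                unit="/".join(unit), genome_length=L,
            )
            iso_rows.extend(clusters)
            if clusters:
                degr.append(
                    _isoforms.degradation_orientation(
                        ts, clusters, tol=config.tol, unit="/".join(unit), genome_length=L
                    )
                )
        _isoforms.isoform_table(iso_rows, L).to_csv(out / "isoforms.tsv", sep="\t", index=False)
        report["isoforms"] = {
            "n_clusters": len(iso_rows),
            "degradation": {
                d.unit: {"orientation": d.orientation, "n_truncated": d.n_truncated}
                for d in degr
            },
        }

    # --- regulatory inference ----------------------------------------------
    if config.regulatory:
        piles = _regulatory.end_pileups(
            classified, annotation, min_site_support=config.min_site_support, tol=config.tol
        )
        calls = _regulatory.call_tis_tts(piles, annotation)
        with open(out / "sites.tsv", "w") as fh:
            fh.write("position\tstrand\tend_type\tsupport\tin_CR\tcall\n")
            for s in calls:
                fh.write(
                    f"{s.position}\t{s.strand}\t{s.end_type}\t{s.support}\t"
                    f"{s.in_CR or '.'}\t{s.call}\n"
                )
        model = _regulatory.build_transcription_model(
            calls, classified, annotation, cov if config.coverage else None
        )
        with open(out / "transcription_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        report["regulatory"] = {
            "n_tis": sum(len(m.tis) for m in model.strands.values()),
            "n_tts": sum(len(m.tts) for m in model.strands.values()),
        }

    # --- rearrangement -------------------------------------------------------
    if config.rearrange:
        order = GeneOrder.from_annotation(annotation)
        ancestral = ancestral_insect_order()
        blocks = shared_adjacency_blocks(order, ancestral)
        flips = strand_flips(order, ancestral)
        report["rearrangement"] = {
            "n_shared_blocks": len(blocks),
            "n_block_genes": sum(len(b) for b in blocks),
            "blocks": [b.genes for b in blocks],
            "strand_flips": flips,
            "breakpoint_distance": breakpoint_distance(order, ancestral),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", out / "report.json")
    return report
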