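"""End-to-end orchestration: build-refs -> detect -> call -> catch -> features.

The pipeline is a pure function of (inputs, parameters, seeds); every run
writes a provenance JSON next to its outputs.  Stage failures propagate
with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .caller import (CircCatalog, classify_catalog, collapse,
                     coverage_profile, reads_to_candidates)
from .catcher import presence_matrix
from .features import canonical_check, catalog_stats, flanking_similarity, polyA_detect
from .gene_model import GeneModel, build_rotations, parse_gene_record
from .junctions import DetectorParams, JunctionDetector
from .seqio import read_fastq, write_bed, write_fasta, write_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    gene_record: str | Path = ""
    fastq_dir: str | Path = ""
    out_dir: str | Path = "nanocirc_out"
    seed_k: int = 15
    min_flank: int = 10
    keyword_k: int = 20
    presence_threshold: int = 1
    collapse_tolerance: int = 0
    search_rc: bool = True
    max_mismatches: int = 0
    min_support: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: str(v) if isinstance(v, Path) else v for k, v in d.items()}


def _provenance(config: RunConfig) -> dict:
    return {
        "tool": "nanocirc",
        "version": __version__,
        "python": platform.python_version(),
        "parameters": config.to_dict(),
    }


def barcode_fastqs(fastq_dir) -> dict[str, Path]:
    """Barcode label -> FASTQ path for every ``*.fastq`` in a directory."""
    return {p.stem: p for p in sorted(Path(fastq_dir).glob("*.fastq"))}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the per-stage outputs in memory and
    writes catalog/matrix/feature tables plus provenance under
    ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    # -- build-refs ---------------------------------------------------------
    def _refs():
        model = parse_gene_record(str(config.gene_record))
        rotations = build_rotations(model)
        write_fasta([(r.name, r.sequence) for r in rotations],
                    out_dir / "rotations.fasta")
        return model, rotations
    model, rotations = stage("build-refs", _refs)

    # -- detect -------------------------------------------------------------
    def _detect():
        fastqs = barcode_fastqs(config.fastq_dir)
        if not fastqs:
            raise FileNotFoundError(f"no FASTQ files in {config.fastq_dir}")
        det = JunctionDetector(rotations, DetectorParams(
            seed_k=config.seed_k, min_flank=config.min_flank,
            search_rc=config.search_rc))
        per_barcode = {}
        for barcode, path in fastqs.items():
            per_barcode[barcode] = det.align_all(read_fastq(path))
        write_table(detections_table(per_barcode), out_dir / "detections.tsv")
        return fastqs, per_barcode
    fastqs, alignments = stage("detect", _detect)

    # -- call ---------------------------------------------------------------
    def _call():
        candidates = []
        all_alns = []
        for barcode, alns in alignments.items():
            candidates.extend(reads_to_candidates(alns, model, barcode))
            all_alns.extend(alns)
        catalog = collapse(candidates, model,
                           tolerance=config.collapse_tolerance,
                           provenance=_provenance(config))
        # support filter acts per BSJ (the validated unit): records whose
        # BSJ totals fewer reads than min_support are dropped together
        bsj_support: dict[tuple, int] = {}
        for r in catalog.records:
            key = (r.acceptor, r.donor)
            bsj_support[key] = bsj_support.get(key, 0) + r.total_support
        catalog.records = [
            r for r in catalog.records
            if bsj_support[(r.acceptor, r.donor)] >= config.min_support]
        coverage = coverage_profile(all_alns, model)
        classify_catalog(catalog, model, coverage)
        write_table(catalog.to_frame(), out_dir / "catalog.tsv")
        write_bed(catalog.to_bed(), out_dir / "catalog.bed")
        return catalog
    catalog = stage("call", _call)

    # -- catch --------------------------------------------------------------
    def _catch():
        matrix = presence_matrix(
            catalog, fastqs, threshold=config.presence_threshold,
            k=config.keyword_k, search_rc=config.search_rc,
            max_mismatches=config.max_mismatches)
        matrix.counts.to_csv(out_dir / "presence_counts.tsv", sep="\t")
        matrix.render().to_csv(out_dir / "presence.tsv", sep="\t")
        return matrix
    matrix = stage("catch", _catch)

    # -- features -----------------------------------------------------------
    def _features():
        feats = feature_table(catalog, model)
        write_table(feats, out_dir / "features.tsv")
        summary = catalog_stats(catalog=catalog, genome=model.sequence,
                                offset=model.locus.start)
        (out_dir / "stats.json").write_text(json.dumps(
            dataclasses.asdict(summary), indent=2))
        return feats, summary
    feats, summary = stage("features", _features)

    (out_dir / "provenance.json").write_text(
        json.dumps(_provenance(config), indent=2))
    return {
        "model": model, "rotations": rotations, "alignments": alignments,
        "catalog": catalog, "matrix": matrix, "features": feats,
        "summary": summary,
    }


def detections_table(per_barcode: dict) -> pd.DataFrame:
    rows = []
    for barcode, alns in per_barcode.items():
        for a in alns:
            for j in a.junctions:
                rows.append({
                    "barcode": barcode, "read_id": a.read_id,
                    "rotation": a.reference, "orientation": a.orientation,
                    "kind": j.kind, "donor": j.donor, "acceptor": j.acceptor,
                    "flank_up": j.flanks[0], "flank_down": j.flanks[1],
                    "ambiguity": j.ambiguity, "traversals": a.traversals,
                })
    cols = ["barcode", "read_id", "rotation", "orientation", "kind",
            "donor", "acceptor", "flank_up", "flank_down", "ambiguity",
            "traversals"]
    return pd.DataFrame(rows, columns=cols)


def feature_table(catalog: CircCatalog, model: GeneModel) -> pd.DataFrame:
    """Per-record BSJ features: canonical sites, similarity motif, poly(A)."""
    genome = model.sequence
    offset = model.locus.start
    rows = []
    for rec in catalog:
        try:
            canonical = canonical_check(genome, rec.donor, rec.acceptor,
                                        offset=offset)
        except Exception:
            canonical = None
        motif = flanking_similarity(genome, rec.donor, rec.acceptor,
                                    offset=offset)
        tracts = polyA_detect(rec.sequence) if rec.sequence else []
        rows.append({
            "circ_id": rec.circ_id,
            "start": rec.acceptor, "end": rec.donor,
            "canonical_bsj": canonical,
            "similarity": motif.motif if motif else "",
            "similarity_len": motif.length if motif else 0,
            "polyA_tracts": len(tracts),
            "polyA_max_len": max((t.length for t in tracts), default=0),
            "polyA_at_bsj": any(t.at_bsj for t in tracts),
            "labels": ";".join(sorted(rec.labels)),
        })
    return pd.DataFrame(rows)
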