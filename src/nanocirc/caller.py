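"""Assembly of junction-bearing reads into a circRNA catalog.

Each read carrying a back-splice junction becomes one candidate whose
internal structure is the set of exactly anchored genomic intervals between
the acceptor and the donor.  Candidates with identical BSJ and structure
are collapsed (coordinate tolerance 0 by default — BSJs were validated by
resequencing, exactness is the contract), support is summed per barcode,
and records are classified into isoform types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import features as _features
from .gene_model import GeneModel, GenomicInterval
from .junctions import ReadAlignment, SpliceJunction

logger = logging.getLogger(__name__)

MICROEXON_MAX = 27          # common literature cutoff for microexons, nt
CRYPTIC_DEPTH_FACTOR = 3.0  # mean segment depth vs median intronic depth


@dataclass
class CircRNARecord:
    """A called circRNA: BSJ, internal structure, labels, support."""

    circ_id: str
    chromosome: str
    bsj: SpliceJunction                      # kind == 'back'
    structure: list[GenomicInterval]         # genomic order, 0-based half-open
    forward_junctions: list[SpliceJunction] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)
    support: dict[str, int] = field(default_factory=dict)
    sequence: str = ""
    read_ids: list[str] = field(default_factory=list)

    @property
    def acceptor(self) -> int:
        """1-based inclusive start of the circle (Table-style convention)."""
        return self.bsj.acceptor

    @property
    def donor(self) -> int:
        return self.bsj.donor

    @property
    def total_support(self) -> int:
        return sum(self.support.values())

    def structure_key(self) -> tuple:
        return tuple((iv.start, iv.end) for iv in self.structure)

    def key(self) -> tuple:
        return (self.bsj.acceptor, self.bsj.donor, self.structure_key())


@dataclass
class CircCatalog:
    records: list[CircRNARecord]
    gene_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def barcodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            for b in r.support:
                seen.setdefault(b)
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a table with 1-based inclusive coordinates."""
        barcodes = self.barcodes()
        rows = []
        for r in self.records:
            row = {
                "circ_id": r.circ_id,
                "chrom": r.chromosome,
                "start": r.acceptor,
                "end": r.donor,
                "n_segments": len(r.structure),
                "structure": ";".join(f"{iv.start1}-{iv.end1}" for iv in r.structure),
                "labels": ";".join(sorted(r.labels)),
                "ambiguity": r.bsj.ambiguity,
                "sequence": r.sequence,
            }
            for b in barcodes:
                row[f"support:{b}"] = r.support.get(b, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_bed(self) -> list[tuple]:
        """BED6 tuples (0-based half-open) for :func:`nanocirc.seqio.write_bed`."""
        return [
            (r.chromosome, r.acceptor - 1, r.donor, r.circ_id,
             min(1000, r.total_support), "+")
            for r in self.records
        ]


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

def _shift_equivalent(left: SpliceJunction, other: SpliceJunction) -> bool:
    """True when ``other`` is ``left`` shifted within its ambiguity window
    (same junction drawn at another position of an identical repeat)."""
    shift = other.acceptor - left.acceptor
    return (other.donor - left.donor == shift
            and 0 <= shift <= max(left.ambiguity, other.ambiguity))


def reads_to_candidates(alignments: Sequence[ReadAlignment],
                        model: GeneModel,
                        barcode: str = "sample",
                        min_circle: int = 20) -> list[CircRNARecord]:
    """One circRNA candidate per read with a back-splice junction.

    Reads whose back junctions disagree (two different BSJs in one read —
    chimeric PCR artifacts are likelier than double circles) are excluded
    and logged.  Rolling-circle passes over the same BSJ collapse to one
    unit of support.  Circles spanning fewer than ``min_circle`` nt (the
    two exact BSJ flanks must fit inside the circle) are noise artifacts
    and dropped.
    """
    out = []
    for aln in alignments:
        backs = [j for j in aln.back_junctions
                 if j.donor - j.acceptor + 1 >= min_circle]
        if not backs:
            continue
        # junctions shifted within an identical-flank repeat are the same
        # BSJ; the leftmost placement is canonical
        leftmost = min(backs, key=lambda j: (j.acceptor, j.donor))
        if not all(_shift_equivalent(leftmost, j) for j in backs):
            logger.warning("read %s supports distinct BSJs; excluded",
                           aln.read_id)
            continue
        bsj = leftmost
        chrom = model.locus.chromosome
        intervals = [GenomicInterval(chrom, s, e) for s, e in aln.segments]
        # clip anchored intervals to the circle span [acceptor, donor]
        lo, hi = bsj.acceptor - 1, bsj.donor
        clipped = [
            GenomicInterval(iv.chromosome, max(iv.start, lo), min(iv.end, hi))
            for iv in intervals
            if min(iv.end, hi) > max(iv.start, lo)
        ]
        forwards = []
        seen_fwd = set()
        for j in aln.forward_junctions:
            if j.key not in seen_fwd:
                seen_fwd.add(j.key)
                forwards.append(j)
        out.append(CircRNARecord(
            circ_id=aln.read_id,
            chromosome=model.locus.chromosome,
            bsj=bsj,
            structure=clipped,
            forward_junctions=sorted(forwards, key=lambda j: j.key),
            support={barcode: 1},
            read_ids=[aln.read_id],
        ))
    return out


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def _within(a: CircRNARecord, b: CircRNARecord, tol: int) -> bool:
    if abs(a.bsj.acceptor - b.bsj.acceptor) > tol:
        return False
    if abs(a.bsj.donor - b.bsj.donor) > tol:
        return False
    if len(a.structure) != len(b.structure):
        return False
    return all(
        abs(x.start - y.start) <= tol and abs(x.end - y.end) <= tol
        for x, y in zip(a.structure, b.structure)
    )


def collapse(candidates: Sequence[CircRNARecord],
             model: GeneModel | None = None,
             tolerance: int = 0,
             provenance: dict | None = None) -> CircCatalog:
    """Merge candidates sharing BSJ and structure (within ``tolerance`` nt);
    support sums per barcode; records ordered by (acceptor, donor)."""
    merged: list[CircRNARecord] = []
    for cand in sorted(candidates, key=lambda c: c.key()):
        target = None
        if tolerance == 0:
            for rec in merged:
                if rec.key() == cand.key():
                    target = rec
                    break
        else:
            for rec in merged:
                if _within(rec, cand, tolerance):
                    target = rec
                    break
        if target is None:
            merged.append(CircRNARecord(
                circ_id=cand.circ_id,
                chromosome=cand.chromosome,
                bsj=cand.bsj,
                structure=list(cand.structure),
                forward_junctions=list(cand.forward_junctions),
                support=dict(cand.support),
                read_ids=list(cand.read_ids),
            ))
        else:
            for b, n in cand.support.items():
                target.support[b] = target.support.get(b, 0) + n
            target.read_ids.extend(cand.read_ids)
    merged.sort(key=lambda r: r.key())
    gene_id = model.gene_id if model is not None else ""
    for i, rec in enumerate(merged, start=1):
        rec.circ_id = f"circ-{gene_id or 'gene'}-{i}"
        if model is not None:
            rec.sequence = circle_sequence(rec, model)
    return CircCatalog(records=merged, gene_id=gene_id,
                       provenance=provenance or {})


def circle_sequence(record: CircRNARecord, model: GeneModel) -> str:
    """Reconstructed circle sequence, linearised at the acceptor."""
    return "".join(model.subsequence(iv) for iv in record.structure)


# ---------------------------------------------------------------------------
# single-exon detection and classification
# ---------------------------------------------------------------------------

def _extended_exon_spans(model: GeneModel) -> list[tuple[int, int]]:
    """Per exon: span extended through its flanking introns (0-based)."""
    spans = []
    for i, ex in enumerate(model.exons):
        lo = model.exons[i - 1].end if i > 0 else model.locus.start
        hi = model.exons[i + 1].start if i + 1 < len(model.exons) else model.locus.end
        spans.append((lo, hi))
    return spans


def detect_single_exon(alignments: Sequence[ReadAlignment],
                       model: GeneModel,
                       barcode: str = "sample") -> list[CircRNARecord]:
    """Candidates whose BSJ donor and acceptor both fall within one
    annotated exon extended by its flanking introns — the automated
    equivalent of spotting head-to-tail wrap-around reads in a browser."""
    out = []
    spans = _extended_exon_spans(model)
    for cand in reads_to_candidates(alignments, model, barcode):
        a0, d0 = cand.bsj.acceptor - 1, cand.bsj.donor - 1
        if any(lo <= a0 < hi and lo <= d0 < hi for lo, hi in spans):
            out.append(cand)
    return out


def coverage_profile(alignments: Sequence[ReadAlignment],
                     model: GeneModel) -> np.ndarray:
    """Per-base read depth over the locus from anchored segments."""
    depth = np.zeros(len(model.locus), dtype=np.int64)
    loc = model.locus.start
    for aln in alignments:
        for gs, ge in aln.segments:
            s = max(0, gs - loc)
            e = min(len(depth), ge - loc)
            if e > s:
                depth[s:e] += 1
    return depth


def classify(record: CircRNARecord, model: GeneModel,
             coverage: np.ndarray | None = None,
             cryptic_factor: float = CRYPTIC_DEPTH_FACTOR,
             microexon_max: int = MICROEXON_MAX,
             polya_min_run: int = 10) -> set[str]:
    """Assign isoform type labels to a record.

    Rules: single-exon — structure overlaps exactly one annotated exon;
    multi-exon — more than one; cryptic-exon — a segment with no annotated
    exon overlap whose mean depth exceeds ``cryptic_factor`` x the median
    intronic depth; truncated/extended-exon — a terminal boundary inside /
    outside an annotated exon; microexon — a segment of at most
    ``microexon_max`` nt; polyA-containing and canonical-BSJ come from the
    BSJ feature annotations.
    """
    labels: set[str] = set()
    exons = model.exons
    overlapped = {
        i for i, ex in enumerate(exons)
        if any(seg.overlap(ex) > 0 for seg in record.structure)
    }
    if len(overlapped) == 1:
        labels.add("single-exon")
    elif len(overlapped) > 1:
        labels.add("multi-exon")

    # cryptic exons: intronic segments backed by depth clearly above the
    # intronic background
    intronic_segments = [
        seg for seg in record.structure
        if all(seg.overlap(ex) == 0 for ex in exons)
    ]
    if intronic_segments:
        if coverage is None:
            labels.add("cryptic-exon")
        else:
            intron_mask = np.ones(len(model.locus), dtype=bool)
            for ex in exons:
                s, e = model.local_interval(ex)
                intron_mask[s:e] = False
            for seg in intronic_segments:
                s, e = model.local_interval(seg)
                intron_mask[s:e] = False
            background = (np.median(coverage[intron_mask])
                          if intron_mask.any() else 0.0)
            threshold = max(cryptic_factor * background, 1.0)
            for seg in intronic_segments:
                s, e = model.local_interval(seg)
                if coverage[s:e].mean() > threshold:
                    labels.add("cryptic-exon")
                    break

    # terminal boundaries: acceptor (circle start) and donor (circle end)
    a0, d0 = record.bsj.acceptor - 1, record.bsj.donor - 1
    for pos, terminal in ((a0, "start"), (d0, "end")):
        idx = model.exon_index_at(pos)
        if idx is None:
            labels.add("extended-exon")
        else:
            ex = exons[idx]
            if (terminal == "start" and pos != ex.start) or \
               (terminal == "end" and pos != ex.end - 1):
                labels.add("truncated-exon")

    if any(len(seg) <= microexon_max for seg in record.structure):
        labels.add("microexon")

    seq = record.sequence or circle_sequence(record, model)
    if _features.polyA_detect(seq, min_run=polya_min_run):
        labels.add("polyA-containing")
    try:
        if _features.canonical_check(model.sequence, record.bsj.donor,
                                     record.bsj.acceptor,
                                     offset=model.locus.start):
            labels.add("canonical-BSJ")
    except _features.ContextError:
        pass
    return labels


def classify_catalog(catalog: CircCatalog, model: GeneModel,
                     coverage: np.ndarray | None = None, **kw) -> CircCatalog:
    for rec in catalog.records:
        rec.labels = classify(rec, model, coverage, **kw)
    return catalog
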