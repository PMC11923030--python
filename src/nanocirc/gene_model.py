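"""Gene locus models and exon-rotated references.

A back-splice junction (BSJ) joins a downstream donor to an upstream
acceptor, so a read crossing it cannot be aligned collinearly against the
plain gene sequence.  Rotating the locus at an exon start — writing the
sequence from that exon's start to the locus end, followed by the sequence
from the locus start to that exon's end, so the pivot exon appears at both
ends — turns every BSJ arc into an ordinary collinear two-block alignment:
the donor-side context lives in the *head* copy and the acceptor-side
context in the duplicated *tail* copy.  One rotation is built per exon.

Internal coordinates are 0-based half-open; user-facing tables are 1-based
inclusive (the convention of published BSJ coordinate tables).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")


class GeneModelError(ValueError):
    """Raised when a gene record violates the model invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open internally."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GeneModelError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def start1(self) -> int:
        """Start in 1-based inclusive coordinates."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """End in 1-based inclusive coordinates (== half-open end)."""
        return self.end

    @classmethod
    def from_1based(cls, chromosome: str, start1: int, end1: int,
                    strand: str = "+") -> "GenomicInterval":
        return cls(chromosome, start1 - 1, end1, strand)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene locus: span, ordered exons, and sense-strand sequence.

    ``exons`` are sorted in transcription order (== genomic order on the
    sense strand after minus-strand normalisation) and are disjoint.
    ``sequence`` covers the locus exactly.
    """

    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.exons:
            raise GeneModelError("gene model requires at least one exon")
        if len(self.sequence) != len(self.locus):
            raise GeneModelError(
                f"sequence length {len(self.sequence)} != locus length {len(self.locus)}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GeneModelError(f"invalid bases in sequence: {sorted(bad)}")
        prev_end = self.locus.start
        for ex in self.exons:
            if ex.start < self.locus.start or ex.end > self.locus.end:
                raise GeneModelError(f"exon {ex} outside locus {self.locus}")
            if ex.start < prev_end:
                raise GeneModelError("exons overlap or are unsorted")
            prev_end = ex.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def to_local(self, genomic_pos: int) -> int:
        """Genomic coordinate -> offset into ``sequence``."""
        if not self.locus.contains(genomic_pos):
            raise GeneModelError(f"position {genomic_pos} outside locus")
        return genomic_pos - self.locus.start

    def local_interval(self, iv: GenomicInterval) -> tuple[int, int]:
        return iv.start - self.locus.start, iv.end - self.locus.start

    def subsequence(self, iv: GenomicInterval) -> str:
        s, e = self.local_interval(iv)
        if s < 0 or e > len(self.sequence):
            raise GeneModelError(f"interval {iv} outside locus")
        return self.sequence[s:e]

    def exon_index_at(self, genomic_pos: int) -> int | None:
        for i, ex in enumerate(self.exons):
            if ex.contains(genomic_pos):
                return i
        return None

    def intron_intervals(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.locus.chromosome, a.end, b.start,
                                           self.locus.strand))
        return out


@dataclass
class RearrangedReference:
    """One exon-rotation of a gene locus with its position->genome map.

    ``sequence`` = locus[pivot exon start:] + locus[:pivot exon end], so the
    pivot exon occurs at both ends.  Positions below ``head_length`` belong
    to the head copy; the rest belong to the duplicated tail copy.
    """

    gene_id: str
    pivot: int
    sequence: str
    head_length: int          # locus length - pivot exon start offset
    locus: GenomicInterval
    pivot_exon: GenomicInterval

    @property
    def name(self) -> str:
        return f"{self.gene_id}|rot{self.pivot}"

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genome(self, position: int) -> tuple[int, str]:
        """Map a rotation position to (genomic coordinate, copy tag)."""
        if position < 0 or position >= len(self.sequence):
            raise GeneModelError(
                f"position {position} out of range for rotation of length {len(self)}"
            )
        if position < self.head_length:
            return self.pivot_exon.start + position, "head"
        return self.locus.start + (position - self.head_length), "tail"

    def base_at_genome(self, genomic_pos: int) -> str | None:
        """Base at a genomic position, or None outside the locus."""
        if genomic_pos >= self.pivot_exon.start:
            idx = genomic_pos - self.pivot_exon.start
            return self.sequence[idx] if idx < self.head_length else None
        if genomic_pos >= self.locus.start:
            return self.sequence[self.head_length
                                 + (genomic_pos - self.locus.start)]
        return None

    def from_genome(self, genomic_pos: int, copy: str = "head") -> int:
        """Inverse of :meth:`to_genome` for a given copy tag."""
        if copy == "head":
            pos = genomic_pos - self.pivot_exon.start
            if 0 <= pos < self.head_length:
                return pos
        elif copy == "tail":
            pos = self.head_length + (genomic_pos - self.locus.start)
            if self.head_length <= pos < len(self.sequence):
                return pos
        raise GeneModelError(
            f"genomic position {genomic_pos} not in {copy} copy of rotation {self.pivot}"
        )


@dataclass
class LinearReference:
    """A plain (unrotated) reference with an identity coordinate map.

    Lets the junction detector run against arbitrary sequences (unit tests,
    oracle comparisons) through the same interface as rotations.
    """

    name: str
    sequence: str
    offset: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genome(self, position: int) -> tuple[int, str]:
        if position < 0 or position >= len(self.sequence):
            raise GeneModelError(f"position {position} out of range")
        return self.offset + position, "head"

    def base_at_genome(self, genomic_pos: int) -> str | None:
        idx = genomic_pos - self.offset
        if 0 <= idx < len(self.sequence):
            return self.sequence[idx]
        return None


def build_rotations(model: GeneModel) -> list[RearrangedReference]:
    """Build one exon-rotated reference per exon of ``model``.

    Rotation *i* is the locus sequence from exon-*i*'s start to the locus
    end concatenated with the locus sequence from the locus start to
    exon-*i*'s end; introns are kept verbatim.  Its length is therefore the
    locus length plus the pivot exon length.
    """
    out = []
    for i, ex in enumerate(model.exons):
        s, e = model.local_interval(ex)
        seq = model.sequence[s:] + model.sequence[:e]
        out.append(
            RearrangedReference(
                gene_id=model.gene_id,
                pivot=i,
                sequence=seq,
                head_length=len(model.sequence) - s,
                locus=model.locus,
                pivot_exon=ex,
            )
        )
    return out


def map_to_genome(ref: RearrangedReference, position: int) -> tuple[int, str]:
    """Functional alias for :meth:`RearrangedReference.to_genome`."""
    return ref.to_genome(position)


# ---------------------------------------------------------------------------
# GenBank-style record I/O
# ---------------------------------------------------------------------------

def parse_gene_record(source) -> GeneModel:
    """Parse a GenBank-style flat file into a :class:`GeneModel`.

    ``source`` may be a path or a file-like object.  The record must carry a
    sequence and at least one ``exon`` feature.  Minus-strand genes are
    reverse-complemented on ingest so the model is always on the gene's
    sense strand; coordinates stay genomic.
    """
    try:
        record = SeqIO.read(source, "genbank")
    except Exception as exc:  # malformed flat file
        raise GeneModelError(f"could not parse GenBank record: {exc}") from exc

    try:
        seq = str(record.seq).upper()
    except Exception as exc:
        raise GeneModelError("record has no sequence") from exc
    if not seq:
        raise GeneModelError("record has no sequence")

    # chromosome / genomic anchor live in the source feature qualifiers
    chrom = record.id or record.name or "chr?"
    locus_start = 0
    for f in record.features:
        if f.type == "source":
            q = f.qualifiers
            chrom = q.get("chromosome", [chrom])[0]
            for note in q.get("note", []):
                if note.startswith("locus_start="):
                    locus_start = int(note.split("=", 1)[1])
    strand = "+"

    exon_feats = [f for f in record.features if f.type == "exon"]
    gene_feats = [f for f in record.features if f.type == "gene"]
    if gene_feats and gene_feats[0].location.strand == -1:
        strand = "-"
    elif exon_feats and all(f.location.strand == -1 for f in exon_feats):
        strand = "-"
    if not exon_feats:
        raise GeneModelError("record has no exon features")

    L = len(seq)
    exons_local = []
    for f in exon_feats:
        s, e = int(f.location.start), int(f.location.end)
        if s < 0 or e > L:
            raise GeneModelError(f"exon {s}-{e} outside sequence of length {L}")
        exons_local.append((s, e))

    if strand == "-":
        # normalise to sense orientation: reverse-complement the sequence,
        # flip exon coordinates, keep genomic (plus-strand) numbering of the
        # mirrored axis anchored at locus_start.
        seq = str(Seq(seq).reverse_complement())
        exons_local = sorted((L - e, L - s) for s, e in exons_local)
    else:
        exons_local = sorted(exons_local)

    locus = GenomicInterval(chrom, locus_start, locus_start + L, "+")
    exons = [
        GenomicInterval(chrom, locus_start + s, locus_start + e, "+")
        for s, e in exons_local
    ]
    gene_id = record.name or record.id or "gene"
    return GeneModel(gene_id=gene_id, locus=locus, exons=exons, sequence=seq)


def write_gene_record(model: GeneModel, path) -> None:
    """Write a :class:`GeneModel` back to a GenBank-style flat file."""
    rec = SeqRecord(Seq(model.sequence), id=model.gene_id, name=model.gene_id,
                    description=f"{model.gene_id} locus")
    rec.annotations["molecule_type"] = "DNA"
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, len(model.sequence), strand=1), type="source",
            qualifiers={
                "chromosome": [model.locus.chromosome],
                "note": [f"locus_start={model.locus.start}"],
            },
        )
    )
    rec.features.append(
        SeqFeature(FeatureLocation(0, len(model.sequence), strand=1), type="gene",
                   qualifiers={"gene": [model.gene_id]})
    )
    for i, ex in enumerate(model.exons, start=1):
        s, e = model.local_interval(ex)
        rec.features.append(
            SeqFeature(FeatureLocation(s, e, strand=1), type="exon",
                       qualifiers={"number": [str(i)]})
        )
    if hasattr(path, "write"):
        SeqIO.write(rec, path, "genbank")
    else:
        with open(path, "w") as fh:
            SeqIO.write(rec, fh, "genbank")


def gene_record_string(model: GeneModel) -> str:
    buf = _io.StringIO()
    write_gene_record(model, buf)
    return buf.getvalue()
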