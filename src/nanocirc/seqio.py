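"""FASTA/FASTQ/BED/TSV input-output helpers.

Sequence formats go through Biopython; BED6 is written 0-based half-open;
catalog tables are TSV via pandas.  FASTQ quality strings are carried
verbatim (the pipeline never interprets them).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed sequence file."""


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )


def read_fastq(path) -> Iterator[FastqRead]:
    """Iterate reads from a FASTQ file; malformed input raises
    :class:`FormatError` with the offending line number."""
    n = 0
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield FastqRead(title.split()[0], seq.upper(), qual)
                n += 1
        except ValueError as exc:
            raise FormatError(f"{path}: line {4 * n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[FastqRead], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path) -> int:
    """Write (name, sequence) pairs as FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    return SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: Iterable[tuple], path) -> int:
    """Write BED6 lines from (chrom, start, end, name, score, strand)
    tuples; ``start``/``end`` are 0-based half-open."""
    n = 0
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            if end <= start or start < 0:
                raise FormatError(f"invalid BED interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
            n += 1
    return n


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
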