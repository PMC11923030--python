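"""Keyword search of BSJ-spanning sequences in FASTQ sets.

Every called circRNA gets a diagnostic keyword: the 2k-mer spanning its
back-splice junction (k nt of donor-side suffix + k nt of acceptor-side
prefix of the linearised circle, 40 nt total by default).  Scanning each
barcode's FASTQ for those keywords yields a per-sample presence/count
matrix.  Reverse-complement search is on by default (nanopore amplicon
reads are unstranded); matching is exact by default, with an optional
Hamming-distance tolerance for noisy data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import FastqRead, read_fastq, revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 20  # half-width; keyword length 2k = 40 nt


@dataclass(frozen=True)
class BSJKeyword:
    """A BSJ-spanning keyword: suffix of the donor side + prefix of the
    acceptor side of the circle sequence, k nt each."""

    circ_id: str
    keyword: str
    k: int

    def __post_init__(self) -> None:
        if len(self.keyword) != 2 * self.k:
            raise ValueError("keyword length must be 2*k")


@dataclass
class PresenceMatrix:
    """circRNA x sample hit-count matrix with a presence threshold."""

    counts: pd.DataFrame          # rows: circ ids, columns: barcodes
    threshold: int = 1

    def presence(self) -> pd.DataFrame:
        return self.counts >= self.threshold

    def render(self) -> pd.DataFrame:
        """'+'/'-' table in the style of published presence tables."""
        return self.presence().map(lambda v: "+" if v else "-")


def bsj_keyword(record_or_sequence, k: int = DEFAULT_K) -> BSJKeyword:
    """Keyword for one circRNA.

    Accepts a :class:`nanocirc.caller.CircRNARecord` (uses its reconstructed
    circle sequence, which is linearised at the acceptor) or a plain circle
    sequence.  If the circle is shorter than 2k, k shrinks to fit, with a
    warning.
    """
    if isinstance(record_or_sequence, str):
        circ_id, seq = "circ", record_or_sequence
    else:
        circ_id, seq = record_or_sequence.circ_id, record_or_sequence.sequence
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{circ_id}: no circle sequence to build a keyword from")
    if len(seq) < 2 * k:
        k_new = len(seq) // 2
        logger.warning("%s: circle of %d nt shorter than 2k=%d; shrinking k to %d",
                       circ_id, len(seq), 2 * k, k_new)
        k = k_new
    if k < 1:
        raise ValueError(f"{circ_id}: circle too short for any keyword")
    return BSJKeyword(circ_id=circ_id, keyword=seq[-k:] + seq[:k], k=k)


def _contains(read: str, kw: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return kw in read
    m = len(kw)
    for i in range(len(read) - m + 1):
        mism = 0
        for a, b in zip(read[i:i + m], kw):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return True
    return False


def scan_reads(keywords: Sequence[BSJKeyword], reads: Iterable[FastqRead],
               search_rc: bool = True, max_mismatches: int = 0) -> dict[str, int]:
    """Hit counts per keyword over an iterable of reads.

    A read counts at most once per keyword, even if the keyword occurs
    several times (rolling-circle concatemers); counts ignore quality
    strings and read order.
    """
    pairs = []
    for kw in keywords:
        targets = [kw.keyword]
        if search_rc:
            rc = revcomp(kw.keyword)
            if rc != kw.keyword:
                targets.append(rc)
        pairs.append((kw.circ_id, targets))
    counts = {cid: 0 for cid, _ in pairs}
    for read in reads:
        seq = read.sequence
        for cid, targets in pairs:
            if any(_contains(seq, t, max_mismatches) for t in targets):
                counts[cid] += 1
    return counts


def scan_fastq(keywords: Sequence[BSJKeyword], fastq_path,
               search_rc: bool = True, max_mismatches: int = 0) -> dict[str, int]:
    """Hit counts per keyword in one FASTQ file."""
    return scan_reads(keywords, read_fastq(fastq_path),
                      search_rc=search_rc, max_mismatches=max_mismatches)


def presence_matrix(catalog, fastq_by_barcode: Mapping[str, object],
                    threshold: int = 1, k: int = DEFAULT_K,
                    search_rc: bool = True,
                    max_mismatches: int = 0) -> PresenceMatrix:
    """Scan every barcode's FASTQ for every catalog keyword.

    ``fastq_by_barcode`` maps barcode label -> FASTQ path.  A missing file
    drops that column with a warning rather than failing the run.
    """
    if threshold < 1:
        raise ValueError("presence threshold must be >= 1")
    keywords = []
    for rec in catalog:
        try:
            keywords.append(bsj_keyword(rec, k))
        except ValueError as exc:
            logger.warning("no keyword for %s: %s", rec.circ_id, exc)
    data = {}
    for barcode, path in fastq_by_barcode.items():
        if not Path(path).exists():
            logger.warning("barcode %s: FASTQ %s missing; column skipped",
                           barcode, path)
            continue
        data[barcode] = scan_fastq(keywords, path, search_rc=search_rc,
                                   max_mismatches=max_mismatches)
    counts = pd.DataFrame(
        {b: [data[b][kw.circ_id] for kw in keywords] for b in data},
        index=[kw.circ_id for kw in keywords],
    )
    counts.index.name = "circ_id"
    return PresenceMatrix(counts=counts, threshold=threshold)
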