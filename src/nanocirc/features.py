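"""Back-splice junction feature annotation and catalog statistics.

Three annotations recur around BSJs of amplicon-derived circRNAs:

* canonical splice sites — GU immediately downstream of the donor and AG
  immediately upstream of the acceptor (GT/AG in genomic space);
* flanking similarity — the donor and acceptor neighbourhoods often share a
  short (typically 4-12 nt, occasionally 30+ nt) near-identical motif,
  reported with purine (R) / pyrimidine (Y) wildcards at positions where
  the two copies differ within a base class;
* poly(A) tracts — internal adenosine runs, sometimes abutting the BSJ.

Motifs are reported in the RNA alphabet {A,C,G,U,R,Y}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T", "U"}

MIN_MOTIF_LEN = 4           # shorter similarities are not reported
DEFAULT_WINDOW = 50         # nt each side of each back-splice site
MAX_DEGENERATE_FRAC = 0.3   # cap on R/Y positions in a motif


class ContextError(ValueError):
    """Genome context does not cover the requested sites."""


def _to_rna(base: str) -> str:
    return "U" if base == "T" else base


def _pair_symbol(a: str, b: str) -> str | None:
    """Motif symbol for an aligned base pair, or None on a class mismatch."""
    if a == b and a in "ACGT":
        return _to_rna(a)
    if a in PURINES and b in PURINES:
        return "R"
    if a in PYRIMIDINES and b in PYRIMIDINES:
        return "Y"
    return None


@dataclass(frozen=True)
class SimilarityMotif:
    motif: str
    length: int
    donor_interval: tuple[int, int]     # genomic, 1-based inclusive
    acceptor_interval: tuple[int, int]
    exactness: float

    def __post_init__(self) -> None:
        if self.length < MIN_MOTIF_LEN:
            raise ValueError(f"motif shorter than {MIN_MOTIF_LEN} nt")


@dataclass(frozen=True)
class PolyATract:
    start: int      # offset in the circle sequence, 0-based
    length: int
    purity: float
    at_bsj: bool    # tract abuts the (linearised) BSJ


@dataclass
class CatalogSummary:
    n_circrnas: int
    n_distinct_bsjs: int
    n_bsjs_with_similarity: int
    n_canonical_bsjs: int
    per_sample_presence: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_distinct_bsjs > self.n_circrnas:
            raise ValueError("more distinct BSJs than circRNAs")
        if min(self.n_circrnas, self.n_distinct_bsjs,
               self.n_bsjs_with_similarity, self.n_canonical_bsjs) < 0:
            raise ValueError("negative count")


# ---------------------------------------------------------------------------
# flanking similarity
# ---------------------------------------------------------------------------

def flanking_similarity(genome: str, donor: int, acceptor: int,
                        window: int = DEFAULT_WINDOW,
                        min_len: int = MIN_MOTIF_LEN,
                        max_degenerate_frac: float = MAX_DEGENERATE_FRAC,
                        offset: int = 0,
                        degenerate: bool = True) -> SimilarityMotif | None:
    """Longest common (optionally R/Y-degenerate) substring between the
    donor-site and acceptor-site neighbourhoods.

    ``donor``/``acceptor`` are genomic 1-based; ``offset`` is the genomic
    coordinate of ``genome[0]``.  Windows cover ``window`` nt on each side
    of each site.  Motifs below ``min_len`` are not reported; at most
    ``max_degenerate_frac`` of positions may be R/Y.  Ties prefer the motif
    closest to the junction, then the leftmost occurrence.
    """
    d0 = donor - 1 - offset
    a0 = acceptor - 1 - offset
    if d0 < 0 or d0 >= len(genome) or a0 < 0 or a0 >= len(genome):
        raise ContextError("back-splice sites outside the provided context")
    # donor flank: up to `window` nt ending at the donor plus `window` after
    ds = max(0, d0 + 1 - window)
    de = min(len(genome), d0 + 1 + window)
    as_ = max(0, a0 - window)
    ae = min(len(genome), a0 + window)
    x = genome[ds:de].upper()
    y = genome[as_:ae].upper()
    # site index inside each flank, for the proximity tie-break
    site_x = d0 - ds
    site_y = a0 - as_

    best = None  # (-len, proximity, i, j, motif, exact)
    for diag in range(-(len(y) - 1), len(x)):
        i0 = max(0, diag)
        j0 = i0 - diag
        # decompose the diagonal into maximal class-compatible runs
        i, j = i0, j0
        while i < len(x) and j < len(y):
            syms = []
            ri, rj = i, j
            while ri < len(x) and rj < len(y):
                s = _pair_symbol(x[ri], y[rj])
                if s is None or (not degenerate and s in "RY"):
                    break
                syms.append(s)
                ri += 1
                rj += 1
            if len(syms) >= min_len:
                deg_prefix = [0]
                for s in syms:
                    deg_prefix.append(deg_prefix[-1] + (s in "RY"))
                L = len(syms)
                for a in range(L - min_len + 1):
                    for b in range(a + min_len, L + 1):
                        ndeg = deg_prefix[b] - deg_prefix[a]
                        if ndeg > max_degenerate_frac * (b - a):
                            continue
                        xi, yj = i + a, j + a
                        length = b - a
                        prox = (abs(xi + (length - 1) / 2 - site_x)
                                + abs(yj + (length - 1) / 2 - site_y))
                        cand = (-length, prox, xi, yj,
                                "".join(syms[a:b]), 1 - ndeg / length)
                        if best is None or cand < best:
                            best = cand
            i = ri + 1
            j = rj + 1
    if best is None:
        return None
    neg_len, _, xi, yj, motif, exact = best
    length = -neg_len
    g = lambda flank_start, k: offset + flank_start + k + 1
    return SimilarityMotif(
        motif=motif,
        length=length,
        donor_interval=(g(ds, xi), g(ds, xi + length - 1)),
        acceptor_interval=(g(as_, yj), g(as_, yj + length - 1)),
        exactness=exact,
    )


# ---------------------------------------------------------------------------
# canonical sites and poly(A)
# ---------------------------------------------------------------------------

def canonical_check(genome: str, donor: int, acceptor: int,
                    offset: int = 0) -> bool:
    """True iff the 2 nt after the donor are GT and the 2 nt before the
    acceptor are AG (GU-AG in the transcript), gene-sense orientation."""
    d0 = donor - 1 - offset
    a0 = acceptor - 1 - offset
    if d0 + 3 > len(genome) or a0 - 2 < 0 or d0 < 0 or a0 > len(genome):
        raise ContextError("need 2 nt of context beyond each site")
    return genome[d0 + 1:d0 + 3].upper() == "GT" and \
        genome[a0 - 2:a0].upper() == "AG"


def polyA_detect(circle_sequence: str, min_run: int = 10) -> list[PolyATract]:
    """Maximal runs of A of length >= ``min_run`` in a circle sequence
    (linearised at the acceptor, so a tract at either end abuts the BSJ)."""
    seq = circle_sequence.upper()
    out = []
    for m in re.finditer(rf"A{{{min_run},}}", seq):
        out.append(PolyATract(
            start=m.start(),
            length=m.end() - m.start(),
            purity=1.0,
            at_bsj=(m.start() == 0 or m.end() == len(seq)),
        ))
    return out


# ---------------------------------------------------------------------------
# catalog statistics
# ---------------------------------------------------------------------------

def _split_ids(cell: str) -> list[str]:
    return [p.strip() for p in str(cell).split(";") if p.strip()]


def catalog_stats(bsj_table: pd.DataFrame | None = None,
                  presence_table: pd.DataFrame | None = None,
                  catalog=None, genome: str | None = None,
                  offset: int = 0) -> CatalogSummary:
    """Summary counts over a catalog.

    ``bsj_table`` is a table with one row per distinct BSJ: columns
    ``circrna_ids`` (``;``-separated members sharing that BSJ), ``chrom``,
    ``start``, ``end`` (1-based inclusive), ``donor_site``,
    ``acceptor_site`` (RNA dinucleotides) and optional ``similarity``
    (motif of >= 4 nt, absent when none was observed).  ``presence_table``
    has one row per circRNA with '+'/'-' sample columns.  Alternatively a
    :class:`nanocirc.caller.CircCatalog` can be summarised.
    """
    if catalog is not None:
        ids = [r.circ_id for r in catalog.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate circRNA ids in catalog")
        bsjs = {(r.chromosome, r.acceptor, r.donor) for r in catalog.records}
        canonical = {
            (r.chromosome, r.acceptor, r.donor)
            for r in catalog.records if "canonical-BSJ" in r.labels
        }
        n_sim = 0
        if genome is not None:
            for chrom, acc, don in sorted(bsjs):
                try:
                    motif = flanking_similarity(genome, don, acc, offset=offset)
                except ContextError:
                    motif = None
                if motif is not None:
                    n_sim += 1
        presence = {}
        for b in catalog.barcodes():
            presence[b] = sum(1 for r in catalog.records if r.support.get(b, 0) > 0)
        return CatalogSummary(
            n_circrnas=len(ids),
            n_distinct_bsjs=len(bsjs),
            n_bsjs_with_similarity=n_sim,
            n_canonical_bsjs=len(canonical),
            per_sample_presence=presence,
        )

    if bsj_table is None:
        raise ValueError("need a bsj_table or a catalog")

    all_ids: list[str] = []
    for cell in bsj_table["circrna_ids"]:
        all_ids.extend(_split_ids(cell))
    if len(all_ids) != len(set(all_ids)):
        dupes = sorted({i for i in all_ids if all_ids.count(i) > 1})
        raise ValueError(f"duplicate circRNA ids: {dupes}")

    keys = list(zip(bsj_table["chrom"], bsj_table["start"], bsj_table["end"]))
    distinct = set(keys)

    sim = bsj_table.get("similarity")
    n_sim = 0
    canonical = 0
    seen = set()
    for idx, key in enumerate(keys):
        if key in seen:
            continue
        seen.add(key)
        if sim is not None:
            motif = sim.iloc[idx]
            if isinstance(motif, str) and len(motif.strip()) >= MIN_MOTIF_LEN:
                n_sim += 1
        if (str(bsj_table["donor_site"].iloc[idx]).upper() == "GU"
                and str(bsj_table["acceptor_site"].iloc[idx]).upper() == "AG"):
            canonical += 1

    presence = {}
    if presence_table is not None:
        sample_cols = [c for c in presence_table.columns
                       if c not in {"circrna_id", "accession"}]
        ids = list(presence_table["circrna_id"])
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate circRNA ids in presence table")
        for c in sample_cols:
            presence[c] = int((presence_table[c] == "+").sum())

    return CatalogSummary(
        n_circrnas=len(all_ids),
        n_distinct_bsjs=len(distinct),
        n_bsjs_with_similarity=n_sim,
        n_canonical_bsjs=canonical,
        per_sample_presence=presence,
    )
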