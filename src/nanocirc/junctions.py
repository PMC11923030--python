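"""Splice / back-splice junction detection by exact-anchor chaining.

The strict criterion: a junction is reported only when an unbroken run of
exactly matching bases spans it — by default 10 nt on each side, i.e. one
exact 20-mer across the junction, with no mismatch or indel allowed inside
those flanks.  Anchors are maximal exact matches (MEMs) seeded by shared
k-mers; chains maximise anchored read coverage; junction kind is decided in
genome space after mapping rotation coordinates back (back-splice iff the
acceptor precedes the donor).

Genomically adjacent chained blocks (acceptor == donor + 1) are continuity,
not junctions: this is what lets rolling-circle concatemer reads — whose
reference position wraps at every copy boundary — parse as repeated passes
over the same back-splice junction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .gene_model import LinearReference, RearrangedReference
from .seqio import revcomp

DEFAULT_SEED_K = 15
MIN_SEED_K = 11
DEFAULT_MIN_FLANK = 10
DEFAULT_MAX_READ_GAP = 5


@dataclass(frozen=True)
class AnchorBlock:
    """A maximal exact match between read and reference.

    ``read_start``/``read_end`` are coordinates on the read *in the searched
    orientation* (i.e. on the reverse complement when ``orientation`` is
    '-'); all intervals 0-based half-open.  Exactness (no mismatch, no
    indel) implies equal span lengths.
    """

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.ref_end - self.ref_start:
            raise ValueError("anchor block spans differ: not an exact match")

    def __len__(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class SpliceJunction:
    """A junction between two exactly anchored blocks.

    ``donor`` is the genomic coordinate of the last base of the upstream
    block, ``acceptor`` the first base of the downstream block — both
    1-based, gene-sense.  ``kind`` is 'back' iff acceptor < donor.
    ``flanks`` are the exact run lengths immediately up/downstream of the
    junction; ``ambiguity`` is the number of positions the junction can be
    shifted right without changing the read (identical flank repeats).
    """

    donor: int
    acceptor: int
    kind: str
    flanks: tuple[int, int]
    ambiguity: int = 0

    @property
    def key(self) -> tuple[int, int]:
        return (self.acceptor, self.donor)


@dataclass
class ReadAlignment:
    """Best chain of a read against one rotated reference."""

    read_id: str
    reference: str
    pivot: int | None
    orientation: str
    blocks: list[AnchorBlock]
    junctions: list[SpliceJunction]
    score: int
    traversals: int = 1
    #: anchored genomic spans (0-based half-open), trimmed at junction
    #: placements and merged; the read's footprint on the genome
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def back_junctions(self) -> list[SpliceJunction]:
        return [j for j in self.junctions if j.kind == "back"]

    @property
    def forward_junctions(self) -> list[SpliceJunction]:
        return [j for j in self.junctions if j.kind == "forward"]


# ---------------------------------------------------------------------------
# anchor discovery
# ---------------------------------------------------------------------------

class KmerIndex:
    """k-mer -> positions lookup for one reference sequence."""

    def __init__(self, sequence: str, k: int):
        self.sequence = sequence
        self.k = k
        index: dict[str, list[int]] = {}
        for j in range(len(sequence) - k + 1):
            kmer = sequence[j:j + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(j)
        self._index = index

    def hits(self, kmer: str) -> list[int]:
        return self._index.get(kmer, ())


def _mems_one_strand(read: str, ref_seq: str, index: KmerIndex,
                     orientation: str) -> list[AnchorBlock]:
    """All maximal exact matches of ``read`` against the indexed reference.

    Seeds sharing a diagonal with an already-extended MEM are skipped:
    every exact k-mer on a diagonal lies inside one of its disjoint MEMs.
    N never matches, so anchors cannot cross an N.
    """
    k = index.k
    n, m = len(read), len(ref_seq)
    diag_end: dict[int, int] = {}
    blocks: list[AnchorBlock] = []
    seen: set[tuple[int, int, int]] = set()
    for i in range(n - k + 1):
        kmer = read[i:i + k]
        if "N" in kmer:
            continue
        for j in index.hits(kmer):
            diag = j - i
            if i < diag_end.get(diag, 0):
                continue
            rs, fs = i, j
            while rs > 0 and fs > 0 and read[rs - 1] == ref_seq[fs - 1] != "N":
                rs -= 1
                fs -= 1
            re_, fe = i + k, j + k
            while re_ < n and fe < m and read[re_] == ref_seq[fe] != "N":
                re_ += 1
                fe += 1
            diag_end[diag] = re_
            key = (rs, re_, fs)
            if key not in seen:
                seen.add(key)
                blocks.append(AnchorBlock(rs, re_, fs, fe, orientation))
    blocks.sort(key=lambda b: (b.read_start, b.ref_start))
    return blocks


def find_exact_anchors(read: str, ref, k: int = DEFAULT_SEED_K,
                       index: KmerIndex | None = None,
                       rc_index: bool = True) -> list[AnchorBlock]:
    """Maximal exact-match anchors of ``read`` on a reference, both
    orientations.  ``ref`` is a :class:`RearrangedReference`,
    :class:`LinearReference` or plain sequence.  Reads shorter than ``k``
    yield no blocks."""
    if k < MIN_SEED_K:
        raise ValueError(f"seed length {k} < minimum {MIN_SEED_K}")
    ref_seq = ref if isinstance(ref, str) else ref.sequence
    read = read.upper()
    if index is None or index.k != k:
        index = KmerIndex(ref_seq, k)
    blocks = _mems_one_strand(read, ref_seq, index, "+")
    if rc_index:
        blocks += _mems_one_strand(revcomp(read), ref_seq, index, "-")
    blocks.sort(key=lambda b: (b.orientation, b.read_start, b.ref_start))
    return blocks


# ---------------------------------------------------------------------------
# chaining and junction calling
# ---------------------------------------------------------------------------

def _best_chain(blocks: Sequence[AnchorBlock],
                max_read_gap: int) -> tuple[list[AnchorBlock], int]:
    """Highest-scoring chain (score = anchored read nt, overlaps counted
    once).  Blocks must strictly advance on the read; the reference may jump
    anywhere (forward = splice, backward = new rolling-circle pass).
    Ties: fewer blocks, then lexicographically smallest reference starts."""
    bs = sorted(blocks, key=lambda b: (b.read_start, b.read_end, b.ref_start))
    n = len(bs)
    if n == 0:
        return [], 0
    # per node: score (anchored read nt), raw anchor nt (prefers maximal
    # extensions, which carry the leftmost-placement information for
    # ambiguous junctions), nblocks, refpath, predecessor
    best: list[tuple[int, int, int, tuple, int]] = []

    def rank(c):
        # coverage, then fewest blocks (no redundant repeat blocks), then
        # maximal raw extension (leftmost-placement information), then
        # leftmost reference starts
        return (c[0], -c[2], c[1], tuple(-r for r in c[3]))

    for i, b in enumerate(bs):
        cand = (len(b), len(b), 1, (b.ref_start,), -1)
        for j in range(i):
            a = bs[j]
            if b.read_start <= a.read_start or b.read_end <= a.read_end:
                continue
            gap = b.read_start - a.read_end
            if gap > max_read_gap:
                continue
            overlap = max(0, -gap)
            if overlap >= len(b) or overlap >= len(a):
                continue
            pj = best[j]
            cand2 = (pj[0] + len(b) - overlap, pj[1] + len(b),
                     pj[2] + 1, pj[3] + (b.ref_start,), j)
            if rank(cand2) > rank(cand):
                cand = cand2
        best.append(cand)
    end = max(range(n), key=lambda i: rank(best[i]))
    chain = []
    i = end
    while i != -1:
        chain.append(bs[i])
        i = best[i][4]
    chain.reverse()
    return chain, best[end][0]


def _uncovered_regions(read_len: int, chain: Sequence[AnchorBlock]) -> list[tuple[int, int]]:
    regions = []
    pos = 0
    for b in chain:
        if b.read_start > pos:
            regions.append((pos, b.read_start))
        pos = max(pos, b.read_end)
    if pos < read_len:
        regions.append((pos, read_len))
    return regions


def _rescue_anchors(read: str, ref_seq: str, chain: Sequence[AnchorBlock],
                    rescue_index: KmerIndex,
                    orientation: str) -> list[AnchorBlock]:
    """Re-seed read regions the primary chain left uncovered with a shorter
    seed (the minimum flank), so exact flanks below the primary seed length
    remain discoverable."""
    out = []
    seen = set()
    k_rescue = rescue_index.k
    n, m = len(read), len(ref_seq)
    for a, b in _uncovered_regions(len(read), chain):
        # a neighbouring block's ambiguity extension can absorb part of a
        # junction flank; widen the window so such flanks stay seedable
        a = max(0, a - k_rescue)
        b = min(n, b + k_rescue)
        if b - a < k_rescue:
            continue
        window = read[a:b]
        for blk in _mems_one_strand(window, ref_seq, rescue_index, orientation):
            # re-extend to maximality over the full read: window edges must
            # not clip the block, or ambiguous junctions shift rightward
            rs, fs = blk.read_start + a, blk.ref_start
            re_, fe = blk.read_end + a, blk.ref_end
            while rs > 0 and fs > 0 and read[rs - 1] == ref_seq[fs - 1] != "N":
                rs -= 1
                fs -= 1
            while re_ < n and fe < m and read[re_] == ref_seq[fe] != "N":
                re_ += 1
                fe += 1
            key = (rs, re_, fs)
            if key not in seen:
                seen.add(key)
                out.append(AnchorBlock(rs, re_, fs, fe, orientation))
    return out


def _canonical_shift(ref, gdon0: int, gacc0: int) -> tuple[int, int]:
    """Leftmost placement of a junction in genome space.

    A junction (donor last base ``gdon0``, acceptor first base ``gacc0``,
    0-based) can be drawn one base to the left whenever the donor-end base
    equals the base preceding the acceptor — the read is identical either
    way.  Returns (left shift applied, width of the full ambiguity window).
    """
    base = getattr(ref, "base_at_genome", None)
    if base is None:
        return 0, 0
    t = 0
    while True:
        x, y = base(gdon0 - t), base(gacc0 - 1 - t)
        if x is None or y is None or x != y:
            break
        t += 1
    r = 0
    while True:
        x, y = base(gdon0 + 1 + r), base(gacc0 + r)
        if x is None or y is None or x != y:
            break
        r += 1
    return t, t + r


def _emit_junctions(chain: Sequence[AnchorBlock], ref, read: str,
                    min_flank_up: int, min_flank_down: int
                    ) -> tuple[list[SpliceJunction], dict[int, tuple[int, int]]]:
    """Junctions of a chain plus, per block pair index, the read split
    position and the genome-level shift applied to canonicalise it."""
    junctions = []
    splits: dict[int, tuple[int, int]] = {}
    base = getattr(ref, "base_at_genome", lambda _pos: None)
    # a block crossing the rotation seam is a head-to-tail wrap-around:
    # genomic locus end joined to locus start
    head_len = getattr(ref, "head_length", None)
    for b in chain:
        if head_len is not None and b.ref_start < head_len < b.ref_end:
            up = head_len - b.ref_start
            down = b.ref_end - head_len
            if up >= min_flank_up and down >= min_flank_down:
                gdon, _ = ref.to_genome(head_len - 1)
                gacc, _ = ref.to_genome(head_len)
                t, amb = _canonical_shift(ref, gdon, gacc)
                junctions.append(SpliceJunction(
                    donor=gdon - t + 1, acceptor=gacc - t + 1, kind="back",
                    flanks=(up, down), ambiguity=amb))
    for idx, (prev, nxt) in enumerate(zip(chain, chain[1:])):
        gap = nxt.read_start - prev.read_end
        if gap > 0:
            continue  # inserted bases break the exact run across the junction
        lo = max(nxt.read_start, prev.read_start + min_flank_up)
        hi = min(prev.read_end, nxt.read_end - min_flank_down)
        if lo > hi:
            continue  # flanks below the strict minimum
        s = lo  # leftmost valid split supported by the anchors
        donor0 = prev.ref_start + (s - prev.read_start) - 1
        acceptor0 = nxt.ref_start + (s - nxt.read_start)
        gdon, _ = ref.to_genome(donor0)
        gacc, _ = ref.to_genome(acceptor0)
        if gacc == gdon + 1:
            continue  # genomic continuity (copy-boundary wrap, not a junction)
        # homopolymer slippage: if the whole upstream flank is one repeated
        # base and the genome run continues past the donor, the donor is
        # indistinguishable anywhere in the run — pin it to the run end
        # (where a flank with outside context would pin it)
        run_char = base(gdon)
        slide = 0
        if run_char is not None and base(gdon + 1) == run_char and \
                all(read[i] == run_char for i in range(prev.read_start, s)):
            while base(gdon + 1 + slide) == run_char:
                slide += 1
            gdon += slide
        # canonicalise in genome space: anchor extents depend on which
        # reference copy was matched, the genome does not
        t, amb = _canonical_shift(ref, gdon, gacc)
        gdon -= t
        gacc -= t
        if gacc == gdon + 1:
            continue
        kind = "back" if gacc <= gdon else "forward"
        splits[idx] = (s, slide - t, t)
        junctions.append(SpliceJunction(
            donor=gdon + 1, acceptor=gacc + 1, kind=kind,
            flanks=(s - prev.read_start, nxt.read_end - s),
            ambiguity=amb))
    return junctions, splits


def _genomic_segments(chain: Sequence[AnchorBlock], ref,
                      splits: dict[int, tuple[int, int, int]]
                      ) -> list[tuple[int, int]]:
    """Genomic footprint of a chain: block spans trimmed at (canonical)
    junction splits, split at the rotation seam, merged when
    overlapping/adjacent."""
    head_len = getattr(ref, "head_length", None)
    pieces = []
    for i, b in enumerate(chain):
        eff_start, acc_shift = b.read_start, 0
        if i - 1 in splits:
            eff_start, _, acc_shift = splits[i - 1]
        eff_end, end_delta = b.read_end, 0
        if i in splits:
            eff_end, end_delta, _ = splits[i]
        eff_start = max(eff_start, b.read_start)
        eff_end = min(eff_end, b.read_end)
        if eff_end <= eff_start:
            continue
        rs = b.ref_start + (eff_start - b.read_start)
        re_ = b.ref_start + (eff_end - b.read_start)
        spans = [(rs, re_)]
        if head_len is not None and rs < head_len < re_:
            spans = [(rs, head_len), (head_len, re_)]
        gspans = []
        for s, e in spans:
            gs, _ = ref.to_genome(s)
            gspans.append([gs, gs + (e - s)])
        # canonical junction placement moves the boundary: the
        # acceptor-side span grows left by the shift, the donor-side span
        # end follows the (slid, shifted) donor coordinate
        gspans[0][0] -= acc_shift
        gspans[-1][1] += end_delta
        pieces.extend((s, e) for s, e in gspans if e > s)
    pieces.sort()
    merged: list[list[int]] = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def chain_and_call(blocks: Sequence[AnchorBlock], ref, read: str,
                   min_flank_up: int = DEFAULT_MIN_FLANK,
                   min_flank_down: int = DEFAULT_MIN_FLANK,
                   max_read_gap: int = DEFAULT_MAX_READ_GAP,
                   read_id: str = "read",
                   rescue: bool = True,
                   rescue_index: KmerIndex | None = None) -> ReadAlignment:
    """Chain anchors of one orientation and call junctions.

    ``blocks`` must all share one orientation; ``read`` is the read sequence
    in that orientation.  An empty block list yields an empty alignment.
    """
    orientations = {b.orientation for b in blocks}
    if len(orientations) > 1:
        raise ValueError("chain_and_call expects blocks of one orientation")
    orientation = orientations.pop() if orientations else "+"
    ref_seq = ref if isinstance(ref, str) else ref.sequence
    if isinstance(ref, str):
        ref = LinearReference("ref", ref_seq)

    chain, score = _best_chain(blocks, max_read_gap)
    if rescue:
        if rescue_index is None:
            rescue_index = KmerIndex(ref_seq, min(min_flank_up, min_flank_down))
        extra = _rescue_anchors(read.upper(), ref_seq, chain, rescue_index,
                                orientation)
        if extra:
            chain, score = _best_chain(list(blocks) + extra, max_read_gap)

    junctions, splits = _emit_junctions(chain, ref, read.upper(),
                                        min_flank_up, min_flank_down)
    segments = _genomic_segments(chain, ref, splits)
    aln = ReadAlignment(
        read_id=read_id,
        reference=getattr(ref, "name", "ref"),
        pivot=getattr(ref, "pivot", None),
        orientation=orientation,
        blocks=list(chain),
        junctions=junctions,
        score=score,
        segments=segments,
    )
    aln.traversals = detect_traversals(aln)
    return aln


def detect_traversals(alignment: ReadAlignment) -> int:
    """Number of complete passes over the same back-splice junction in one
    read (rolling-circle copies).  A read contributes one unit of BSJ
    support regardless of its traversal count."""
    counts = Counter(j.key for j in alignment.back_junctions)
    if not counts:
        return 1
    return max(counts.values())


# ---------------------------------------------------------------------------
# per-read detection against all rotations
# ---------------------------------------------------------------------------

@dataclass
class DetectorParams:
    seed_k: int = DEFAULT_SEED_K
    min_flank: int = DEFAULT_MIN_FLANK
    max_read_gap: int = DEFAULT_MAX_READ_GAP
    search_rc: bool = True


class JunctionDetector:
    """Aligns reads against every rotation and keeps the single best one.

    Ties in score go to fewer junctions, then the lowest pivot index, then
    the plus orientation — reproducibility over discovery order.
    """

    def __init__(self, references: Sequence, params: DetectorParams | None = None):
        self.references = list(references)
        self.params = params or DetectorParams()
        self._indexes = [KmerIndex(r.sequence, self.params.seed_k)
                         for r in self.references]
        self._rescue_indexes = [KmerIndex(r.sequence, self.params.min_flank)
                                for r in self.references]

    def align_read(self, read_id: str, sequence: str) -> ReadAlignment | None:
        p = self.params
        sequence = sequence.upper()
        best: ReadAlignment | None = None
        best_key = None
        for ref, idx, ridx in zip(self.references, self._indexes,
                                  self._rescue_indexes):
            blocks = find_exact_anchors(sequence, ref, p.seed_k, index=idx,
                                        rc_index=p.search_rc)
            for orient in ("+", "-"):
                obs = [b for b in blocks if b.orientation == orient]
                if not obs:
                    continue
                oriented = sequence if orient == "+" else revcomp(sequence)
                aln = chain_and_call(
                    obs, ref, oriented,
                    min_flank_up=p.min_flank, min_flank_down=p.min_flank,
                    max_read_gap=p.max_read_gap, read_id=read_id,
                    rescue_index=ridx)
                pivot = aln.pivot if aln.pivot is not None else 0
                key = (-aln.score, len(aln.junctions), pivot,
                       0 if orient == "+" else 1)
                if best is None or key < best_key:
                    best, best_key = aln, key
        return best

    def align_all(self, reads: Iterable) -> list[ReadAlignment]:
        out = []
        for r in reads:
            aln = self.align_read(r.read_id, r.sequence)
            if aln is not None:
                out.append(aln)
        return out
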