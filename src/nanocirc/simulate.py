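"""Seeded simulator for divergent-primer circRNA amplicon sequencing.

The generator emulates the experimental design this pipeline targets: a
single gene locus, circRNAs built from its segments (full exons, truncated
or extended exons, retained introns, cryptic exons, planted BSJ-flank
similarity motifs, poly(A) tracts, canonical GT/AG sites), amplified with
divergent primers so every amplicon is a linearised — possibly
rolling-circle concatemeric — copy of a circle, read out per barcode with
i.i.d. substitution/insertion/deletion noise.

The noise model is i.i.d. per base; real nanopore error is not (it
truncates homopolymers in particular), so an optional homopolymer-shortening
mode geometrically trims A-runs.  Identical config + seed give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel, GenomicInterval
from .seqio import FastqRead, revcomp

BASES = "ACGT"
DEFAULT_BARCODES = tuple(f"BC{i:02d}" for i in range(1, 8))  # 7 cell lines


@dataclass
class CircSpec:
    """Recipe for one planted circRNA.

    ``exons`` are 0-based exon indices; with ``retain_introns`` the circle
    is the single genomic interval from the first to the last chosen exon.
    ``acceptor_shift`` > 0 truncates the first segment from the left;
    ``donor_shift`` < 0 truncates the last segment from the right (positive
    values extend into the flanking intron).  ``cryptic`` intervals are
    extra locus-relative segments.  ``motif_len`` plants one copy of a
    random motif ending at the donor (inside the circle) and one ending
    just before the acceptor (outside), the retained-copy geometry seen in
    real flank-similarity BSJs.  ``polya_len`` overwrites the donor-side
    circle end with adenosines.  ``barcodes`` maps barcode -> reads (None:
    every configured barcode at the default depth).
    """

    name: str
    exons: Sequence[int]
    retain_introns: bool = False
    acceptor_shift: int = 0
    donor_shift: int = 0
    cryptic: Sequence[tuple[int, int]] = ()
    motif_len: int = 0
    polya_len: int = 0
    canonical: bool = False
    barcodes: dict[str, int] | None = None


@dataclass
class SimConfig:
    seed: int = 0
    n_exons: int = 7
    exon_len: tuple[int, int] = (80, 250)
    intron_len: tuple[int, int] = (150, 600)
    flank_len: int = 200
    splice_signals: bool = True
    barcodes: Sequence[str] = DEFAULT_BARCODES
    reads_per_circ: int = 10
    copy_number_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    random_orientation: bool = True
    homopolymer_shorten: bool = False
    circ_specs: Sequence[CircSpec] | None = None

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("noise rates must be in [0, 1)")
        if self.n_exons < 1:
            raise ValueError("need at least one exon")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthCirc:
    name: str
    acceptor: int                      # 1-based inclusive (circle start)
    donor: int                        # 1-based inclusive (circle end)
    structure: list[GenomicInterval]
    sequence: str
    spec: CircSpec

    @property
    def key(self) -> tuple:
        return (self.acceptor, self.donor,
                tuple((iv.start, iv.end) for iv in self.structure))


@dataclass
class TruthSet:
    model: GeneModel
    circs: list[TruthCirc]
    design: pd.DataFrame               # circ x barcode read counts
    reads: pd.DataFrame | None = None  # per-read provenance, after simulate_reads

    def circ(self, name: str) -> TruthCirc:
        return next(c for c in self.circs if c.name == name)


# ---------------------------------------------------------------------------
# gene synthesis
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_gene(config: SimConfig, rng: np.random.Generator | None = None,
              gene_id: str = "simgene", chromosome: str = "chrS",
              locus_start: int = 10_000) -> GeneModel:
    """Random gene locus with the configured exon/intron structure and
    (optionally) GT/AG splice signals at annotated intron boundaries."""
    rng = config.rng() if rng is None else rng
    pieces = []
    exon_bounds = []
    pos = 0
    pieces.append(_random_seq(rng, config.flank_len))
    pos += config.flank_len
    for i in range(config.n_exons):
        if i > 0:
            ilen = int(rng.integers(*config.intron_len, endpoint=True))
            intron = _random_seq(rng, ilen)
            if config.splice_signals and ilen >= 4:
                intron = "GT" + intron[2:-2] + "AG"
            pieces.append(intron)
            pos += ilen
        elen = int(rng.integers(*config.exon_len, endpoint=True))
        exon_bounds.append((pos, pos + elen))
        pieces.append(_random_seq(rng, elen))
        pos += elen
    pieces.append(_random_seq(rng, config.flank_len))
    pos += config.flank_len
    seq = "".join(pieces)
    locus = GenomicInterval(chromosome, locus_start, locus_start + pos)
    exons = [GenomicInterval(chromosome, locus_start + s, locus_start + e)
             for s, e in exon_bounds]
    return GeneModel(gene_id=gene_id, locus=locus, exons=exons, sequence=seq)


# ---------------------------------------------------------------------------
# circRNA truth sets
# ---------------------------------------------------------------------------

def default_circ_specs(model: GeneModel) -> list[CircSpec]:
    """Ten circRNAs mirroring the isoform classes seen in targeted
    amplicon studies: single-exon with intronic flanks, spliced multi-exon,
    intron-retained, poly(A)-bearing (two sharing one BSJ), 3'-truncated,
    cryptic-exon, microexon, and flank-similarity motifs of 6-30 nt."""
    ex = model.exons
    loc = model.locus.start

    def L(i):  # locus-relative exon bounds
        return ex[i].start - loc, ex[i].end - loc

    n = len(ex)
    if n < 6:
        raise ValueError("default truth set needs at least 6 exons")
    i34_lo, i34_hi = L(3)[1], L(4)[0]           # intron between exons 3 and 4
    mid = (i34_lo + i34_hi) // 2
    e4len = L(4)[1] - L(4)[0]
    specs = [
        CircSpec("c1", exons=[1], retain_introns=True,
                 acceptor_shift=-60, donor_shift=60, motif_len=8),
        CircSpec("c2", exons=[2, 3], motif_len=6),
        CircSpec("c3", exons=[3, 4], retain_introns=True, canonical=True),
        CircSpec("c4", exons=list(range(min(7, n))), polya_len=40),
        CircSpec("c5", exons=[i for i in range(min(7, n)) if i != 4],
                 polya_len=19),
        CircSpec("c6", exons=[0, 1, 2], donor_shift=-30),
        CircSpec("c7", exons=[3, 4], cryptic=[(mid - 27, mid + 28)]),
        CircSpec("c8", exons=[4, 5], acceptor_shift=e4len - 24),
        CircSpec("c9", exons=[5], motif_len=12),
        CircSpec("c10", exons=[1, 2], motif_len=30),
    ]
    return specs


def _spec_structure(spec: CircSpec, model: GeneModel) -> list[GenomicInterval]:
    chrom = model.locus.chromosome
    ex = [model.exons[i] for i in sorted(spec.exons)]
    if spec.retain_introns:
        ivs = [[ex[0].start, ex[-1].end]]
    else:
        ivs = [[e.start, e.end] for e in ex]
        for cs, ce in spec.cryptic:
            ivs.append([model.locus.start + cs, model.locus.start + ce])
        ivs.sort()
    ivs[0][0] += spec.acceptor_shift
    ivs[-1][1] += spec.donor_shift
    lo, hi = model.locus.start, model.locus.end
    if not (lo <= ivs[0][0] < ivs[-1][1] <= hi):
        raise ValueError(f"{spec.name}: structure outside locus")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"{spec.name}: overlapping segments")
    return [GenomicInterval(chrom, s, e) for s, e in ivs]


def _canonicalize_structure(ivs: Sequence[GenomicInterval],
                            genome: str, loc: int) -> list[GenomicInterval]:
    """Leftmost placement of every ambiguous boundary.

    When the sequence ending at a donor equals the sequence ending just
    before the matching acceptor, the junction can be drawn anywhere in the
    repeat; the detector reports the leftmost placement, so the truth set
    adopts the same convention.  Applied to the BSJ (circle start/end pair)
    and to every internal boundary pair.
    """
    segs = [[iv.start - loc, iv.end - loc] for iv in ivs]
    chrom = ivs[0].chromosome

    def shift(e_pos: int, s_pos: int, min_e: int, min_s: int) -> int:
        t = 0
        while (e_pos - 1 - t >= min_e and s_pos - 1 - t >= min_s
               and e_pos - 1 - t >= 0 and s_pos - 1 - t >= 0
               and genome[e_pos - 1 - t] == genome[s_pos - 1 - t]):
            t += 1
        return t

    # BSJ: donor end of the last segment pairs with the acceptor start
    t = shift(segs[-1][1], segs[0][0],
              min_e=segs[-1][0] + 1, min_s=0)
    segs[-1][1] -= t
    segs[0][0] -= t
    # internal boundaries: segment i's end pairs with segment i+1's start
    for i in range(len(segs) - 1):
        t = shift(segs[i][1], segs[i + 1][0],
                  min_e=segs[i][0] + 1, min_s=0)
        segs[i][1] -= t
        segs[i + 1][0] -= t
    return [GenomicInterval(chrom, loc + s, loc + e) for s, e in segs]


def make_circs(model: GeneModel, config: SimConfig,
               rng: np.random.Generator | None = None) -> TruthSet:
    """Build the circRNA truth set, planting motifs / poly(A) tracts /
    canonical sites into the genome.  Overlapping edits that would write
    different bases to one position are spec conflicts and raise."""
    rng = config.rng() if rng is None else rng
    specs = list(config.circ_specs) if config.circ_specs is not None \
        else default_circ_specs(model)

    genome = list(model.sequence)
    written: dict[int, str] = {}

    def write(pos0: int, text: str, who: str) -> None:
        # pos0 locus-relative
        if pos0 < 0 or pos0 + len(text) > len(genome):
            raise ValueError(f"{who}: planted edit outside locus")
        for off, ch in enumerate(text):
            p = pos0 + off
            if p in written and written[p] != ch:
                raise ValueError(f"{who}: conflicting edit at locus offset {p}")
            written[p] = ch
            genome[p] = ch

    structures = {}
    for spec in specs:
        structures[spec.name] = _spec_structure(spec, model)
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("duplicate circ spec names")

    loc = model.locus.start
    for spec in specs:
        ivs = structures[spec.name]
        a0 = ivs[0].start - loc            # locus-relative acceptor
        d_end = ivs[-1].end - loc          # locus-relative donor end (half-open)
        if spec.motif_len:
            motif = _random_seq(rng, spec.motif_len)
            write(d_end - spec.motif_len, motif, spec.name)   # retained copy
            write(a0 - spec.motif_len, motif, spec.name)      # spliced-out copy
        if spec.polya_len:
            write(d_end - spec.polya_len, "A" * spec.polya_len, spec.name)
            # pin the run boundaries so the tract length is defined
            if d_end < len(genome) and genome[d_end] == "A":
                write(d_end, "G", spec.name)
            start = d_end - spec.polya_len - 1
            if genome[start] == "A" and start not in written:
                write(start, "C", spec.name)
        if spec.canonical:
            write(d_end, "GT", spec.name)
            write(a0 - 2, "AG", spec.name)
            # keep the junction unambiguous so the canonical sites stay
            # exactly at the annotated BSJ
            if genome[d_end - 1] == "G":
                write(d_end - 1, "C", spec.name)

    model = GeneModel(gene_id=model.gene_id, locus=model.locus,
                      exons=model.exons, sequence="".join(genome))

    circs = []
    for spec in specs:
        ivs = _canonicalize_structure(structures[spec.name], model.sequence,
                                      model.locus.start)
        seq = "".join(model.subsequence(iv) for iv in ivs)
        circs.append(TruthCirc(
            name=spec.name,
            acceptor=ivs[0].start + 1,
            donor=ivs[-1].end,
            structure=ivs,
            sequence=seq,
            spec=spec,
        ))

    rows = {}
    for c in circs:
        per = c.spec.barcodes if c.spec.barcodes is not None else {
            b: config.reads_per_circ for b in config.barcodes}
        rows[c.name] = {b: per.get(b, 0) for b in config.barcodes}
    design = pd.DataFrame(rows).T.reindex(columns=list(config.barcodes)).fillna(0)
    design = design.astype(int)
    design.index.name = "circ"
    return TruthSet(model=model, circs=circs, design=design)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def apply_noise(seq: str, rng: np.random.Generator, sub: float, ins: float,
                dele: float) -> tuple[str, int, int, int]:
    """i.i.d. per-base noise; returns (noisy sequence, #sub, #ins, #del)."""
    if sub == ins == dele == 0:
        return seq, 0, 0, 0
    out = []
    n_sub = n_ins = n_del = 0
    u = rng.random(len(seq))
    for i, base in enumerate(seq):
        r = u[i]
        if r < dele:
            n_del += 1
            continue
        if r < dele + sub:
            base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4] \
                if base in BASES else base
            n_sub += 1
        out.append(base)
        if rng.random() < ins:
            out.append(BASES[int(rng.integers(0, 4))])
            n_ins += 1
    return "".join(out), n_sub, n_ins, n_del


def _shorten_homopolymers(seq: str, rng: np.random.Generator,
                          min_run: int = 8, p: float = 0.3) -> str:
    """Geometrically trim long A-runs — a caricature of the homopolymer
    undercall of nanopore basecallers."""
    import re
    out, last = [], 0
    for m in re.finditer(rf"A{{{min_run},}}", seq):
        out.append(seq[last:m.start()])
        cut = int(rng.geometric(1 - p)) - 1
        out.append("A" * max(min_run, (m.end() - m.start()) - cut))
        last = m.end()
    out.append(seq[last:])
    return "".join(out)


def _primer_phase(circ: TruthCirc, model: GeneModel,
                  rng: np.random.Generator,
                  min_segment: int = 60) -> int:
    """Linearisation point: inside the middle third of a circle segment
    that overlaps an annotated exon (divergent primers anneal in exons;
    segments below ``min_segment`` nt cannot host a divergent pair)."""
    offsets = []
    pos = 0
    for iv in circ.structure:
        if len(iv) >= min_segment and any(iv.overlap(e) > 0
                                          for e in model.exons):
            third = len(iv) // 3
            offsets.append((pos + third, pos + 2 * third))
        pos += len(iv)
    if not offsets:
        return int(rng.integers(0, len(circ.sequence)))
    lo, hi = offsets[int(rng.integers(0, len(offsets)))]
    return int(rng.integers(lo, max(lo + 1, hi)))


def simulate_reads(truth: TruthSet, config: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> dict[str, list[FastqRead]]:
    """Per-barcode FASTQ reads for a truth set; also fills
    ``truth.reads`` with per-read provenance (circ, copies, edit counts)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    copies, probs = zip(*sorted(config.copy_number_probs.items()))
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()

    per_barcode: dict[str, list[FastqRead]] = {b: [] for b in config.barcodes}
    rows = []
    for circ in truth.circs:
        for barcode in config.barcodes:
            n = int(truth.design.loc[circ.name, barcode])
            for i in range(n):
                k = int(rng.choice(copies, p=probs))
                phase = _primer_phase(circ, truth.model, rng)
                template = (circ.sequence[phase:]
                            + circ.sequence * (k - 1)
                            + circ.sequence[:phase])
                if config.homopolymer_shorten:
                    template = _shorten_homopolymers(template, rng)
                seq, n_sub, n_ins, n_del = apply_noise(
                    template, rng, config.sub_rate, config.ins_rate,
                    config.del_rate)
                orient = "+"
                if config.random_orientation and rng.random() < 0.5:
                    seq = revcomp(seq)
                    orient = "-"
                rid = f"{circ.name}|{barcode}|{i}"
                per_barcode[barcode].append(
                    FastqRead(rid, seq, "I" * len(seq)))
                rows.append({
                    "read_id": rid, "circ": circ.name, "barcode": barcode,
                    "copies": k, "phase": phase, "orientation": orient,
                    "template_len": len(template),
                    "n_sub": n_sub, "n_ins": n_ins, "n_del": n_del,
                })
    truth.reads = pd.DataFrame(rows)
    return per_barcode


def simulate(config: SimConfig) -> tuple[TruthSet, dict[str, list[FastqRead]]]:
    """End-to-end: gene -> truth set -> per-barcode reads, one seed."""
    rng = config.rng()
    model = make_gene(config, rng)
    truth = make_circs(model, config, rng)
    reads = simulate_reads(truth, config, rng)
    return truth, reads
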