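# Methods

## Rotated references

A back-splice junction (BSJ) joins genomic coordinate $d$ (donor, last
base of the circle) to $a < d$ (acceptor, first base). No linear aligner
sees this as a collinear alignment against the gene. We therefore build
one *rotation* per exon: rotation $i$ = locus$[s_i:L]$ + locus$[0:e_i]$,
where $[s_i, e_i)$ is exon $i$ — the pivot exon is present at both ends
and introns are kept verbatim (targeted circRNAs retain intronic
segments, so exon-only concatenation would lose them). In rotation
coordinates every position below the *head length* $L - s_i$ maps to
genome position $s_i +$ offset ("head"); the rest maps from the locus
start ("tail"). A BSJ arc then decomposes into a head block (donor side)
followed by a tail block (acceptor side) — an ordinary forward jump in
rotation space. The rotation convention (pivot at exon starts, tail
ending at the pivot exon end) is a choice; rotating at preceding intron
boundaries would work identically for detection.

## Junction detection

**Criterion.** A splice or back-splice junction is accepted only if an
unbroken run of exactly matching bases spans it: by default 10 nt on each
side (one exact 20-mer across the junction), exposed as two per-side
parameters (`min_flank_up/down`). No mismatch, insertion or deletion is
tolerated inside the flanks; this is deliberately conservative, trading
per-read sensitivity for coordinate exactness, and is recovered
statistically by read depth.

**Anchoring.** Maximal exact matches (MEMs) are found by hashing
reference $k$-mers ($k = 15$ by default, minimum 11) and extending seed
hits to maximality; seeds falling inside an already-extended MEM on the
same diagonal are skipped, making discovery linear per diagonal. `N`
matches nothing, so anchors never cross an `N`. Both read orientations
are searched (nanopore amplicon reads are unstranded); the reverse
orientation is normalised to gene sense before reporting.

**Chaining.** Dynamic programming selects the chain maximising anchored
read coverage; blocks must advance strictly on the read (gap ≤ 5 nt
absorbs nanopore indels at block edges; bounded overlap is allowed and
counted once), while the reference coordinate may jump forward (splice)
or backward (a new rolling-circle pass). Ties prefer fewer blocks, then
maximal raw anchor length, then leftmost reference starts — the
raw-length preference matters because a block anchored at the very start
of a rotation cannot extend left, whereas its copy in the duplicated tail
can, and that extension carries the junction-placement information.

**Gap rescue.** Exact flanks of 10–14 nt cannot contain a 15-mer seed, so
read regions left uncovered by the primary chain (widened by one rescue
seed length on each side, because a neighbouring block's ambiguity
extension can absorb part of a flank) are re-searched with seed length =
`min_flank` and re-extended to maximality over the whole read.

**Junction emission and canonical placement.** For consecutive chained
blocks with read gap 0, the leftmost split satisfying both flank minima
is taken; genomically adjacent blocks (acceptor = donor + 1) are
continuity — this is how a concatemer read's wrap at the copy boundary
parses silently. The placement of a junction flanked by an identical
repeat is ambiguous; we canonicalise in *genome* space, shifting left
while the donor-end base equals the base preceding the acceptor, and
report the ambiguity window width. One special case is read-aware: when
the entire upstream flank is a single repeated base (a poly(A) tract
participating in the BSJ) the donor is indistinguishable anywhere inside
the homopolymer run and is pinned to the run end, where reads with
outside context pin it. The symmetric acceptor-side case is not handled
(no realistic configuration produces it; a circle would have to *begin*
with a homopolymer that also precedes its acceptor).

**Rotation choice.** Every read is aligned against every rotation and
both orientations; the single best-scoring combination is kept (ties:
fewer junctions, lowest pivot index, plus orientation).

## circRNA calling

Each read with a back junction becomes one candidate. Back junctions
repeated by rolling-circle passes, or drawn at shifted positions of the
same ambiguity window, are one BSJ; a read whose back junctions genuinely
disagree is excluded as a likely chimeric PCR artifact rather than split
into two circles. Back junctions spanning < 20 nt are dropped (both exact
flanks must fit inside the circle). The candidate's structure is the set
of anchored genomic segments between acceptor and donor, trimmed at the
canonical junction splits and merged; collapsing is exact by default
(tolerance 0 — BSJs in this assay class are confirmed by resequencing, so
exactness is the contract), with an integer tolerance for noisy use.
Support is per barcode; one read is one unit regardless of traversals.

Classification rules: single-exon (structure overlaps exactly one
annotated exon), multi-exon (> 1), truncated-exon (a terminal boundary
strictly inside an annotated exon), extended-exon (a terminal boundary in
an intron), cryptic-exon (an intronic segment whose mean depth exceeds
3× the median intronic depth — the published criterion is qualitative,
"above intronic background, below annotated exons", so the factor is a
configurable choice), microexon (a segment ≤ 27 nt, a common literature
convention; no published cutoff exists for this assay), poly(A)-containing
and canonical-BSJ from the feature annotations.

The pipeline's `min_support` filter acts on BSJ-level support (records
sharing a BSJ are kept or dropped together): under exact collapsing at
5% error a true circle fragments into many structure-level variants, and
the BSJ is the validated unit.

## BSJ features

* **Canonical check**: GT immediately after the donor and AG immediately
  before the acceptor (GU–AG in the transcript), evaluated in gene-sense
  orientation.
* **Flanking similarity**: longest common substring between the donor and
  acceptor neighbourhoods (window 50 nt each side — chosen to contain the
  longest observed motifs, 30 and 37 nt, with margin) under optional R/Y
  degeneracy: positions differing within the purine or pyrimidine class
  are reported as R/Y, capped at 30% of motif positions (an uncapped
  degenerate match is trivially long); motifs < 4 nt are not reported.
  Ties prefer the motif closest to the junction, then leftmost. Only R/Y
  classes are used, not full IUPAC, matching how such motifs are printed.
* **Poly(A)**: maximal A-runs ≥ 10 nt (purity 1.0) in the circle sequence
  linearised at the acceptor; a tract touching either end abuts the BSJ.

## Simulator

The generator emulates the targeted assay: a random gene locus (default 7
exons of 80–250 nt, introns 150–600 nt, 200 nt outer flanks, GT/AG at
annotated intron boundaries — an amplicon-scale analogue of the real
multi-kilobase locus), a 10-circRNA default truth set covering the
observed isoform classes (single-exon with intronic flanks, spliced
multi-exon, intron-retained with canonical GT/AG, two poly(A) circles of
40 and 19 nt sharing one BSJ, a 3′-truncated circle, a cryptic-exon
circle, a microexon circle, and flank-similarity motifs of 6, 8, 12 and
30 nt), and per-barcode reads: each read is a rotation of the circle
sequence opened inside the middle third of an exon-overlapping segment of
≥ 60 nt (divergent primers anneal in exons and cannot fit in a
microexon), concatemerised with copy-number distribution
{1: 0.5, 2: 0.3, 3: 0.2}, and noised i.i.d. per base (defaults 3%
substitution, 1% insertion, 1% deletion = the 5% total used in the
stochastic validation; 7 barcodes × 10 reads per circRNA).

Planted motifs follow the retained-copy geometry seen in real data: one
copy ends at the donor (inside the circle), the identical copy ends just
before the acceptor (spliced out), so the circle carries exactly one
copy. Poly(A) tracts overwrite the donor-side circle end, with the base
on each side of the run pinned non-A so the planted tract length is
well-defined. Canonical specs plant GT/AG and pin the donor-end base so
the annotated junction stays unambiguous. Overlapping edits writing
different bases are spec conflicts and raise.

Truth coordinates are canonicalised with the same leftmost rule as the
detector (both the BSJ and every internal boundary), so "exact recovery"
is well-defined even when a planted motif makes the BSJ placement
ambiguous — the published account of this ambiguity is that such BSJs
cannot be annotated uniquely at all; we fix the convention instead.

**What a green test does not establish.** The noise model is i.i.d. per
base; real nanopore error is context-dependent and notoriously truncates
homopolymers (an optional mode geometrically trims A-runs as a
caricature). PCR chimeras, barcode cross-talk and coverage bias are not
modelled. Zero-noise exactness and 5%-noise recall on this world say
nothing about basecaller-specific artifacts.

## Numerical/degenerate-input choices

* Internal coordinates 0-based half-open; all tables 1-based inclusive;
  BED 0-based half-open. Minus-strand gene records are
  reverse-complemented to sense on ingest.
* Reads shorter than the seed yield no anchors; an empty block list yields
  an empty alignment; an empty catalog writes valid empty outputs.
* A circle shorter than 2k shrinks its keyword with a warning; a record
  with no usable keyword is skipped by the matrix builder with a warning.
* A missing barcode FASTQ drops that column with a warning rather than
  failing the run; malformed FASTQ is rejected with a line number.
* Determinism: every simulation consumes a single seeded generator; the
  detector's tie-breaks are total orders; pipeline reruns are
  byte-identical.

## Known limitations

* Junction flanks are required exact, so sensitivity per read falls
  roughly like $(1-e)^{20}$ with error rate $e$; depth compensates.
* BSJs whose flanks sit inside long repeats (≥ the flank length) of the
  same gene can be mis-anchored under noise; the leftmost convention
  resolves ambiguity deterministically but cannot recover a diagonal
  broken by an indel inside the repeat.
* BSJ keywords are assumed specific; after canonicalisation, a BSJ whose
  donor-side flank equals the sequence preceding its acceptor has a
  keyword identical to a contiguous genomic 40-mer, which other isoforms
  of the same gene may contain. Presence calls for such circRNAs
  overcount by construction, exactly as in the keyword-scanning assay
  this mirrors.
* Relative abundance across barcodes is not quantified (amplification is
  primer-pair dependent); the matrix is presence/count only.
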