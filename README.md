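# nanocirc

Targeted discovery of full-length circular RNAs (circRNAs) from long-read
amplicon sequencing.

## The problem

circRNAs are covalently closed transcripts produced by back-splicing: a
downstream donor site is ligated to an upstream acceptor site, producing a
head-to-tail **back-splice junction (BSJ)** that is diagnostic of
circularity. A targeted assay amplifies them with *divergent* primer pairs
(outward-oriented on the linear genome, so only circular or concatemeric
templates yield product), sequences the amplicons on a nanopore device —
one barcode per sample — and must then answer, per gene:

* which BSJs exist, at which exact genomic coordinates;
* the full internal structure of each circRNA isoform (full, truncated or
  extended exons, retained introns, cryptic exons, microexons, internal
  poly(A) tracts);
* which samples express each circRNA.

Standard circRNA callers assume annotated exon boundaries or canonical
GU–AG splice sites; targeted amplicon data is dominated by non-canonical
back-splice sites, so this package makes no such assumption.

## The method

1. **Exon-rotated references** (`build_rotations`). For a gene with exons
   $e_1..e_n$, rotation $i$ is the locus sequence from the start of $e_i$
   to the locus end, concatenated with the locus start through the end of
   $e_i$ — the pivot exon appears at both ends, introns kept verbatim. A
   read arc crossing a BSJ, which wraps around on the genome, becomes an
   ordinary collinear two-block alignment in the right rotation.
2. **Strict exact-anchor junction calling** (`JunctionDetector`). Maximal
   exact matches seeded by shared $k$-mers ($k=15$) are chained
   (read-collinear, reference jumps free, read gap ≤ 5 nt); uncovered read
   windows are re-seeded at the minimum flank length. A junction is
   emitted only when an unbroken exact run covers **≥ 10 nt on each side**
   of it — one exact 20-mer across the junction, no mismatch or indel.
   Junction placement inside an identical-flank repeat is canonicalised to
   the leftmost position in genome space; `kind = back` iff the acceptor
   precedes the donor. Rolling-circle concatemer reads count once per BSJ
   regardless of traversal number.
3. **circRNA calling** (`reads_to_candidates`, `collapse`, `classify`).
   Each BSJ-bearing read becomes a candidate (structure = anchored
   genomic segments between acceptor and donor); identical candidates are
   collapsed with per-barcode support; records are classified
   (single-/multi-exon, truncated/extended exon, cryptic exon by depth
   over the intronic background, microexon ≤ 27 nt, poly(A)-containing,
   canonical GU–AG BSJ).
4. **Keyword presence scanning** (`bsj_keyword`, `presence_matrix`). Each
   circRNA's BSJ-spanning 40-mer (20 nt each side) is searched in every
   barcode's FASTQ, giving a circRNA × sample presence/count matrix.
5. **BSJ features** (`flanking_similarity`, `canonical_check`,
   `polyA_detect`, `catalog_stats`). The donor and acceptor
   neighbourhoods are compared for their longest common substring under
   purine (R) / pyrimidine (Y) degeneracy (reported at ≥ 4 nt, ≤ 30%
   degenerate positions); GU–AG canonicality and internal poly(A) tracts
   are annotated; catalog totals are summarised.
6. **Simulator** (`simulate`). A seeded generator of synthetic gene loci,
   circRNA truth sets with planted features (motifs, poly(A), canonical
   sites, cryptic exons), divergent-primer amplicons with rolling-circle
   concatemers, and i.i.d. substitution/insertion/deletion noise — the
   validation harness for everything above.

Coordinates are 0-based half-open internally; every table and the CLI use
1-based inclusive coordinates; BED output is 0-based half-open.

The package also ships two reference tables transcribed from a published
targeted study of one apoptosis-related gene in 7 colorectal cancer cell
lines (`nanocirc.fixtures`): per-sample presence of 46 circRNAs, and 40
distinct BSJs with coordinates, site dinucleotides and similarity motifs.

## Worked example

```sh
nanocirc simulate --seed 7 --out-dir demo/sim
# wrote 10 circRNAs, 700 reads -> demo/sim
nanocirc run --gene demo/sim/gene.gb --fastq-dir demo/sim \
             --out-dir demo/out --min-support 5
# catalog: 184 circRNAs, 8 distinct BSJs -> demo/out
```

The simulated world plants 10 circRNAs over 8 distinct BSJs (two pairs
share a BSJ with different internal structures) and reads them out at the
default 5% error. The run recovers exactly those 8 BSJs; the 184 records
are their structure-level variants (at 5% error many reads carry a
noise-broken internal segment, and collapsing is exact by default — see
`docs/methods.md`). `demo/out/features.tsv` then shows, per BSJ:

```
         circ_id  start   end  canonical_bsj  similarity_len  polyA_max_len  polyA_at_bsj
 circ-simgene-10  10200 13249          False              10             40          True
 ...
circ-simgene-150  11308 11867           True              10              0         False
```

— the planted canonical GU–AG circle is flagged `canonical_bsj=True`, and
the poly(A)-bearing circle shows its 40-A tract abutting the BSJ.
`demo/out/presence.tsv` is the circRNA × barcode '+'/'−' table.

Catalog totals over the packaged published tables:

```sh
nanocirc stats
# { "n_circrnas": 46, "n_distinct_bsjs": 40,
#   "n_bsjs_with_similarity": 30, "n_canonical_bsjs": 5, ... }
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the catalog statistics over the packaged
tables, a noiseless simulate → detect → call round trip (catalog must
equal the planted truth exactly), and the same round trip at the default
5% error (reporting BSJ recall). All randomness derives from `--seed`.
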