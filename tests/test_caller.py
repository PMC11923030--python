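"""circRNA candidate assembly, collapsing and classification."""

from __future__ import annotations

import numpy as np
import pytest

from nanocirc import (CircRNARecord, GenomicInterval, JunctionDetector,
                      SimConfig, CircSpec, SpliceJunction, build_rotations,
                      classify, collapse, coverage_profile, detect_single_exon,
                      make_circs, make_gene, reads_to_candidates, simulate,
                      simulate_reads)
from nanocirc.junctions import ReadAlignment


def zero_noise_config(**kw):
    kw.setdefault("sub_rate", 0.0)
    kw.setdefault("ins_rate", 0.0)
    kw.setdefault("del_rate", 0.0)
    return SimConfig(**kw)


def align_world(truth, reads):
    det = JunctionDetector(build_rotations(truth.model))
    return {b: det.align_all(rs) for b, rs in reads.items()}


def make_alignment(read_id, junctions, segments, reference="simgene|rot0"):
    return ReadAlignment(read_id=read_id, reference=reference, pivot=0,
                         orientation="+", blocks=[], junctions=junctions,
                         score=0, segments=segments)


def bj(donor, acceptor, amb=0):
    return SpliceJunction(donor=donor, acceptor=acceptor, kind="back",
                          flanks=(20, 20), ambiguity=amb)


class TestCandidates:
    def test_forward_only_read_gives_no_candidate(self, toy_model):
        fwd = SpliceJunction(donor=5200, acceptor=5401, kind="forward",
                             flanks=(20, 20))
        aln = make_alignment("r", [fwd], [(5100, 5200), (5400, 5500)])
        assert reads_to_candidates([aln], toy_model) == []

    def test_conflicting_bsjs_exclude_the_read(self, toy_model, caplog):
        aln = make_alignment("chimera", [bj(5500, 5101), bj(5900, 5401)],
                             [(5100, 5500)])
        with caplog.at_level("WARNING"):
            out = reads_to_candidates([aln], toy_model)
        assert out == []
        assert "excluded" in caplog.text

    def test_shift_equivalent_bsjs_are_one_junction(self, toy_model):
        # same BSJ drawn at two placements of a 3 nt repeat
        aln = make_alignment("rc", [bj(5500, 5101, amb=3), bj(5503, 5104)],
                             [(5100, 5500)])
        (cand,) = reads_to_candidates([aln], toy_model)
        assert (cand.bsj.donor, cand.bsj.acceptor) == (5500, 5101)

    def test_same_bsj_different_structure_stays_distinct(self, toy_model):
        a1 = make_alignment("r1", [bj(5950, 5101)], [(5100, 5200), (5400, 5950)])
        a2 = make_alignment("r2", [bj(5950, 5101)], [(5100, 5200), (5800, 5950)])
        cands = reads_to_candidates([a1, a2], toy_model)
        cat = collapse(cands, toy_model)
        assert len(cat) == 2
        assert len({(r.acceptor, r.donor) for r in cat.records}) == 1

    def test_zero_noise_truth_set_recovered_exactly(self):
        config = zero_noise_config(seed=101, reads_per_circ=3,
                                   barcodes=["BC01"])
        truth, reads = simulate(config)
        cands = []
        for b, alns in align_world(truth, reads).items():
            cands.extend(reads_to_candidates(alns, truth.model, b))
        cat = collapse(cands, truth.model)
        called = {(r.acceptor, r.donor, r.structure_key()) for r in cat.records}
        expected = {c.key for c in truth.circs}
        assert called == expected
        # support conservation: every BSJ-bearing read lands in a record
        assert sum(r.total_support for r in cat.records) == len(cands)


class TestCollapse:
    def _cand(self, read_id, donor, acceptor, segs, barcode="BC01"):
        return CircRNARecord(
            circ_id=read_id, chromosome="chrT", bsj=bj(donor, acceptor),
            structure=[GenomicInterval("chrT", s, e) for s, e in segs],
            support={barcode: 1}, read_ids=[read_id])

    def test_identical_candidates_merge_with_summed_support(self, toy_model):
        cands = [self._cand(f"r{i}", 5500, 5101, [(5100, 5500)])
                 for i in range(3)]
        cat = collapse(cands, toy_model)
        assert len(cat) == 1
        assert cat.records[0].support == {"BC01": 3}

    def test_barcodes_kept_separate_in_one_record(self, toy_model):
        cands = [self._cand("r1", 5500, 5101, [(5100, 5500)], "BC01"),
                 self._cand("r2", 5500, 5101, [(5100, 5500)], "BC02")]
        cat = collapse(cands, toy_model)
        assert len(cat) == 1
        assert cat.records[0].support == {"BC01": 1, "BC02": 1}

    def test_tolerance_zero_vs_two_on_near_identical_candidates(self, toy_model):
        cands = [self._cand("r1", 5500, 5101, [(5100, 5500)]),
                 self._cand("r2", 5501, 5102, [(5101, 5501)])]
        assert len(collapse(cands, toy_model, tolerance=0)) == 2
        assert len(collapse(cands, toy_model, tolerance=2)) == 1

    def test_ordering_and_ids_deterministic(self, toy_model, rng):
        cands = [self._cand(f"r{i}", 5500 + 10 * i, 5101, [(5100, 5500 + 10 * i)])
                 for i in range(4)]
        perm = list(rng.permutation(len(cands)))
        cat1 = collapse([cands[i] for i in perm], toy_model)
        cat2 = collapse(cands, toy_model)
        assert [(r.circ_id, r.acceptor, r.donor) for r in cat1.records] == \
            [(r.circ_id, r.acceptor, r.donor) for r in cat2.records]


class TestSingleExon:
    def test_exon_with_intronic_flanks_is_single_exon(self):
        config = zero_noise_config(seed=101, reads_per_circ=2,
                                   barcodes=["BC01"])
        truth, reads = simulate(config)
        alns = align_world(truth, reads)["BC01"]
        singles = detect_single_exon(alns, truth.model)
        names = {c.read_ids[0].split("|")[0] for c in singles}
        # c1 = exon 1 +- 60 nt intronic flanks, wrap-around reads
        assert "c1" in names and "c9" in names
        # c2 spans two exons: never a single-exon call
        assert "c2" not in names

    def test_overlapping_single_exon_circles_stay_distinct(self):
        """Several overlapping single-exon circles with distinct BSJs give
        distinct records (the highly-overlapping single-exon case)."""
        config = zero_noise_config(seed=7, reads_per_circ=2, barcodes=["BC01"])
        model = make_gene(config)
        e = model.exons[3]
        L = len(e)
        specs = [CircSpec(f"s{i}", exons=[3], retain_introns=True,
                          acceptor_shift=-sh, donor_shift=sh)
                 for i, sh in enumerate((0, 15, 33, 52))]
        config.circ_specs = specs
        truth = make_circs(model, config)
        reads = simulate_reads(truth, config)
        alns = align_world(truth, reads)["BC01"]
        singles = detect_single_exon(alns, truth.model)
        cat = collapse(singles, truth.model)
        assert len(cat) == 4
        assert len({(r.acceptor, r.donor) for r in cat.records}) == 4


@pytest.fixture(scope="module")
def world():
    config = zero_noise_config(seed=101, reads_per_circ=3, barcodes=["BC01"])
    truth, reads = simulate(config)
    alns = align_world(truth, reads)["BC01"]
    cands = reads_to_candidates(alns, truth.model, "BC01")
    cat = collapse(cands, truth.model)
    coverage = coverage_profile(alns, truth.model)
    by_name = {}
    for rec in cat.records:
        name = rec.read_ids[0].split("|")[0]
        rec.labels = classify(rec, truth.model, coverage)
        by_name[name] = rec
    return truth, by_name


class TestClassify:
    def test_multi_exon_exact_boundaries(self, world):
        truth, recs = world
        assert "multi-exon" in recs["c2"].labels
        assert "single-exon" not in recs["c2"].labels

    def test_truncated_exon(self, world):
        _, recs = world
        assert "truncated-exon" in recs["c6"].labels  # 3'-truncated last exon
        assert "truncated-exon" in recs["c8"].labels

    def test_cryptic_exon_needs_depth_over_intron_background(self, world):
        truth, recs = world
        assert "cryptic-exon" in recs["c7"].labels
        assert "cryptic-exon" not in recs["c2"].labels

    def test_microexon(self, world):
        _, recs = world
        assert "microexon" in recs["c8"].labels  # 24 nt first segment

    def test_polya_containing(self, world):
        _, recs = world
        assert "polyA-containing" in recs["c4"].labels
        assert "polyA-containing" in recs["c5"].labels
        assert "polyA-containing" not in recs["c2"].labels

    def test_canonical_bsj(self, world):
        _, recs = world
        assert "canonical-BSJ" in recs["c3"].labels
        assert "canonical-BSJ" not in recs["c1"].labels

    def test_single_exon_label(self, world):
        _, recs = world
        assert "single-exon" in recs["c1"].labels
        assert "extended-exon" in recs["c1"].labels  # intronic flanks

    def test_classification_is_read_order_invariant(self):
        config = zero_noise_config(seed=23, reads_per_circ=2, barcodes=["BC01"])
        truth, reads = simulate(config)
        det = JunctionDetector(build_rotations(truth.model))
        rs = reads["BC01"]
        alns_f = det.align_all(rs)
        alns_r = det.align_all(list(reversed(rs)))
        cat_f = collapse(reads_to_candidates(alns_f, truth.model), truth.model)
        cat_r = collapse(reads_to_candidates(alns_r, truth.model), truth.model)
        cov_f = coverage_profile(alns_f, truth.model)
        cov_r = coverage_profile(alns_r, truth.model)
        assert (cov_f == cov_r).all()
        labels_f = [classify(r, truth.model, cov_f) for r in cat_f.records]
        labels_r = [classify(r, truth.model, cov_r) for r in cat_r.records]
        assert labels_f == labels_r
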