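"""BSJ feature annotation: similarity motifs, canonical sites, poly(A),
and catalog statistics over the packaged tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from nanocirc import (SimConfig, canonical_check, catalog_stats,
                      flanking_similarity, polyA_detect, simulate)
from nanocirc.features import ContextError
from nanocirc.fixtures import table1_presence, table2_bsj
from conftest import random_dna

CELL_LINES = ["Caco-2", "COLO 205", "DLD-1", "RKO", "HT-29", "HCT 116",
              "SW 620"]


def plant_flanks(rng, motif_d, motif_a, spacing=400):
    """Genome with ``motif_d`` ending at the donor and ``motif_a`` ending
    just before the acceptor; returns (genome, donor, acceptor) 1-based."""
    g = list(random_dna(rng, 1000))
    donor = 300
    acceptor = 300 + spacing
    g[donor - len(motif_d):donor] = motif_d
    g[acceptor - 1 - len(motif_a):acceptor - 1] = motif_a
    return "".join(g), donor, acceptor


class TestFlankingSimilarity:
    def test_planted_identical_8mer(self, rng):
        motif = random_dna(rng, 8)
        genome, donor, acceptor = plant_flanks(rng, motif, motif)
        m = flanking_similarity(genome, donor, acceptor, window=50)
        assert m is not None
        got = oracles.degenerate_lcs(genome[donor - 50:donor + 50],
                                     genome[acceptor - 51:acceptor + 49])
        assert m.length == got >= 8
        if m.length == 8:
            assert m.exactness == 1.0
            assert m.motif == motif.replace("T", "U")

    def test_unrelated_flanks_below_floor_give_none(self):
        # flanks engineered so no common (degenerate) run reaches 4 nt
        x = "ACAC" * 25
        y = "GAGA" * 25  # A aligns with A only at shifted phases; runs <= 3
        genome = x + "T" * 10 + y
        donor = len(x)  # 1-based: donor at the end of x
        acceptor = len(x) + 11
        m = flanking_similarity(genome, donor, acceptor, window=25,
                                degenerate=False)
        assert oracles.degenerate_lcs(genome[donor - 25:donor + 25],
                                      genome[acceptor - 26:acceptor + 24],
                                      max_degenerate_frac=0.0) < 4 or m
        if oracles.degenerate_lcs(genome[donor - 25:donor + 25],
                                  genome[acceptor - 26:acceptor + 24],
                                  max_degenerate_frac=0.0) < 4:
            assert m is None

    def test_degenerate_12mer_with_two_ry_positions(self, rng):
        base = random_dna(rng, 12)
        other = list(base)
        # introduce purine/purine and pyrimidine/pyrimidine differences
        other[3] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[3]]
        other[8] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[8]]
        other = "".join(other)
        genome, donor, acceptor = plant_flanks(rng, base, other)
        m = flanking_similarity(genome, donor, acceptor, window=30)
        expected = oracles.degenerate_lcs(genome[donor - 30:donor + 30],
                                          genome[acceptor - 31:acceptor + 29])
        assert m.length == expected >= 12
        if m.length == 12:
            assert sum(c in "RY" for c in m.motif) == 2
            assert m.exactness == pytest.approx(10 / 12)

    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_degenerate_lcs(self, seed):
        r = np.random.default_rng(seed)
        genome = random_dna(r, 400)
        donor = int(r.integers(60, 200))
        acceptor = int(r.integers(donor + 10, 340))
        w = int(r.integers(10, 50))
        m = flanking_similarity(genome, donor, acceptor, window=w)
        x = genome[max(0, donor - w):donor + w]
        y = genome[max(0, acceptor - 1 - w):acceptor - 1 + w]
        expected = oracles.degenerate_lcs(x, y)
        assert (m.length if m else 0) == expected

    def test_motif_intervals_point_at_the_planted_copies(self, rng):
        motif = random_dna(rng, 10)
        genome, donor, acceptor = plant_flanks(rng, motif, motif)
        m = flanking_similarity(genome, donor, acceptor)
        if m.length == 10:  # no chance extension
            assert m.donor_interval == (donor - 9, donor)
            assert m.acceptor_interval == (acceptor - 10, acceptor - 1)

    def test_sites_outside_context_rejected(self, rng):
        with pytest.raises(ContextError):
            flanking_similarity(random_dna(rng, 100), 500, 600)


class TestCanonical:
    def test_planted_gt_ag_is_canonical(self, rng):
        g = list(random_dna(rng, 300))
        donor, acceptor = 100, 201  # 1-based
        g[100:102] = "GT"   # 2 nt after the donor
        g[198:200] = "AG"   # 2 nt before the acceptor
        assert canonical_check("".join(g), donor, acceptor) is True

    def test_cc_tt_context_is_not_canonical(self, rng):
        g = list(random_dna(rng, 300))
        g[100:102] = "CC"
        g[198:200] = "TT"
        assert canonical_check("".join(g), 100, 201) is False

    def test_simulated_canonical_fraction_matches_plants(self, rng):
        """Over a catalog with a known planted fraction of GT/AG sites the
        measured canonical fraction equals the planted one."""
        n, planted = 20, 0
        results = []
        for i in range(n):
            g = list(random_dna(rng, 400))
            donor, acceptor = 150, 301
            make_canonical = i % 5 == 0  # 20%
            if make_canonical:
                g[150:152] = "GT"
                g[298:300] = "AG"
            else:
                g[150:152] = "CA"
                g[298:300] = "TC"
            planted += make_canonical
            results.append(canonical_check("".join(g), donor, acceptor))
        assert sum(results) == planted == 4

    def test_insufficient_context_rejected(self, rng):
        with pytest.raises(ContextError):
            canonical_check(random_dna(rng, 50), 49, 10)


class TestPolyA:
    def test_planted_19A_tract(self, rng):
        seq = random_dna(rng, 100).replace("AAA", "ACG") + "A" * 19
        tracts = polyA_detect(seq, min_run=10)
        assert len(tracts) == 1
        assert tracts[0].length == 19
        assert tracts[0].at_bsj  # abuts the circle end == the BSJ

    def test_no_run_above_minimum_gives_empty(self):
        assert polyA_detect("ACGT" * 50, min_run=10) == []

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_longest_run_oracle(self, seed):
        r = np.random.default_rng(seed)
        # A-rich alphabet to generate runs
        seq = "".join("AACGT"[i] for i in r.integers(0, 5, size=500))
        got = [(t.start, t.length) for t in polyA_detect(seq, min_run=5)]
        assert got == oracles.longest_a_runs(seq, 5)


class TestCatalogStats:
    def test_packaged_catalog_totals(self):
        s = catalog_stats(bsj_table=table2_bsj(),
                          presence_table=table1_presence())
        assert s.n_circrnas == 46
        assert s.n_distinct_bsjs == 40
        assert s.n_bsjs_with_similarity == 30
        assert s.n_canonical_bsjs == 5  # 4 exon-exon BSJs + one more

    def test_presence_counts_per_cell_line(self):
        s = catalog_stats(bsj_table=table2_bsj(),
                          presence_table=table1_presence())
        assert set(s.per_sample_presence) == set(CELL_LINES)
        t1 = table1_presence()
        for line in CELL_LINES:
            assert s.per_sample_presence[line] == int((t1[line] == "+").sum())

    def test_fixture_row_for_widely_expressed_circ(self):
        t1 = table1_presence().set_index("circrna_id")
        row = t1.loc["circ-BCL2L12-34"]
        present = [c for c in CELL_LINES if row[c] == "+"]
        assert present == ["COLO 205", "DLD-1", "HT-29", "HCT 116", "SW 620"]

    def test_single_record_catalog(self):
        import pandas as pd
        df = pd.DataFrame({"circrna_ids": ["x"], "chrom": ["c"], "start": [10],
                           "end": [99], "donor_site": ["GU"],
                           "acceptor_site": ["AG"], "similarity": [None]})
        s = catalog_stats(bsj_table=df)
        assert (s.n_circrnas, s.n_distinct_bsjs) == (1, 1)
        assert s.n_bsjs_with_similarity == 0
        assert s.n_canonical_bsjs == 1

    def test_duplicate_ids_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"circrna_ids": ["x", "x"], "chrom": ["c", "c"],
                           "start": [1, 5], "end": [9, 20],
                           "donor_site": ["AU", "AU"],
                           "acceptor_site": ["CC", "CC"]})
        with pytest.raises(ValueError, match="duplicate"):
            catalog_stats(bsj_table=df)

    def test_row_permutation_invariance(self, rng):
        t2 = table2_bsj()
        shuffled = t2.sample(frac=1, random_state=7).reset_index(drop=True)
        a = catalog_stats(bsj_table=t2)
        b = catalog_stats(bsj_table=shuffled)
        assert a == b


class TestMotifRetention:
    def test_one_motif_copy_in_circle_two_in_genome(self):
        """The planted flank motif appears twice in the pre-mRNA but only
        once in the circle sequence (the donor-side copy is retained, the
        acceptor-side copy is spliced out)."""
        from nanocirc.simulate import _spec_structure

        config = SimConfig(seed=55, sub_rate=0, ins_rate=0, del_rate=0,
                           reads_per_circ=1, barcodes=["BC01"])
        truth, _ = simulate(config)
        model = truth.model
        for name, mlen in (("c9", 12), ("c10", 30)):
            circ = truth.circ(name)
            # the planted copy ends at the as-specified donor (the reported
            # BSJ may sit a few bases left of it in the identical repeat)
            spec_ivs = _spec_structure(circ.spec, model)
            d0 = spec_ivs[-1].end - model.locus.start
            motif = model.sequence[d0 - mlen:d0]
            assert model.sequence.count(motif) == 2
            # exactly one copy in the circle, counted cyclically
            doubled = circ.sequence * 2
            L = len(circ.sequence)
            cyclic = sum(1 for i in range(L)
                         if doubled[i:i + mlen] == motif)
            assert cyclic == 1
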