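"""Primer enumeration, weighting, annealing optimization, in-silico PCR."""

import itertools
import math

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from tagback import (
    AnnealingParams,
    Primer,
    PrimerConstraints,
    PrimerOptima,
    enumerate_primers,
    insilico_pcr,
    melting_temperature,
    optimize_primer_set,
    pair_weight,
    primer_weight,
)
from tagback.errors import PrimerRoleError
from tagback.motif import reverse_complement
from tagback.primers import exhaustive_primer_set, set_weight_of

from .conftest import random_dna
from .oracles import naive_pcr, naive_primer_windows


class TestMeltingTemperature:
    def test_matches_independent_nearest_neighbor_oracle(self):
        """Same published parameter set, independent implementation (Biopython)."""
        rng = np.random.default_rng(2)
        for _ in range(40):
            s = random_dna(rng, int(rng.integers(15, 30)))
            if s == reverse_complement(s):
                continue
            expect = mt.Tm_NN(s, nn_table=mt.DNA_NN3, Na=50, dnac1=500, dnac2=0,
                              saltcorr=5)
            assert melting_temperature(s) == pytest.approx(expect, abs=0.1)

    def test_selfcomp_duplex_gets_symmetry_term(self):
        s = "GAATTCGGCCGAATTC"  # its own reverse complement
        expect = mt.Tm_NN(s, nn_table=mt.DNA_NN3, Na=50, dnac1=500, dnac2=0,
                          saltcorr=5, selfcomp=True)
        assert melting_temperature(s) == pytest.approx(expect, abs=0.1)

    def test_reverse_complement_has_identical_tm(self):
        s = "ACGGATCGTTACGGATCGCA"
        assert melting_temperature(s) == pytest.approx(
            melting_temperature(reverse_complement(s)), abs=1e-9
        )

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("A" * 10 + "T" * 10) < melting_temperature(
            "G" * 10 + "C" * 10
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


class TestWeights:
    def test_primer_at_all_optima_weighs_one(self):
        p = Primer("X" * 20, "c", 0, "+", tm=60.0, gc=50.0, weight=0.0)
        assert primer_weight(p) == pytest.approx(1.0)

    def test_tm_offset_closed_form(self):
        p = Primer("X" * 20, "c", 0, "+", tm=62.5, gc=50.0, weight=0.0)
        assert primer_weight(p) == pytest.approx(math.exp(-0.5))

    def test_weight_decreases_with_tm_distance(self):
        ws = [
            primer_weight(Primer("X" * 20, "c", 0, "+", tm=60 + d, gc=50, weight=0))
            for d in (0, 1, 2, 4, 8)
        ]
        assert ws == sorted(ws, reverse=True)

    def test_pair_weight_product_and_dtm_penalty(self):
        f = Primer("GACGATCGATCGATCGATCG", "c", 0, "+", tm=60, gc=50, weight=0.9)
        r = Primer("CATCGGATCGAACGGATCCA", "c", 400, "-", tm=60, gc=50, weight=0.8)
        assert pair_weight(f, r) == pytest.approx(0.72)
        r10 = Primer(r.sequence, "c", 400, "-", tm=70, gc=50, weight=0.8)
        assert pair_weight(f, r10) < 0.01 * 0.72  # exp(-12.5)

    def test_engineered_cross_dimer_applies_factor(self):
        f = Primer("GACGATCGATCGGCCGGCCG", "c", 0, "+", tm=60, gc=50, weight=1.0)
        # reverse primer containing the reverse complement of f's 3' 8-mer
        r = Primer("TT" + reverse_complement(f.sequence[-8:]) + "ACGATCGATG",
                   "c", 300, "-", tm=60, gc=50, weight=1.0)
        assert pair_weight(f, r) == pytest.approx(0.1, rel=1e-6)

    def test_pair_weight_bounded_by_min_primer_weight(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            f = Primer(random_dna(rng, 20), "c", 0, "+",
                       tm=float(rng.uniform(55, 65)), gc=50.0,
                       weight=float(rng.uniform(0.1, 1)))
            r = Primer(random_dna(rng, 20), "c", 500, "-",
                       tm=float(rng.uniform(55, 65)), gc=50.0,
                       weight=float(rng.uniform(0.1, 1)))
            assert pair_weight(f, r) <= min(f.weight, r.weight) + 1e-12


class TestEnumerate:
    def test_region_shorter_than_min_length_is_empty(self):
        assert enumerate_primers("ACGTACGTAGCAGCACA", None) == []

    def test_homopolymer_region_is_empty(self):
        assert enumerate_primers("A" * 120, None) == []

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(8)
        region = random_dna(rng, 500)
        got = sorted(
            (p.start, p.strand, p.sequence)
            for p in enumerate_primers(region, None)
        )
        expect = naive_primer_windows(region, (18, 28), (25.0, 75.0), 4)
        assert got == expect


def _mk(seq, tm, w, start=0, strand="+"):
    return Primer(seq, "c", start, strand, tm=tm, gc=50.0, weight=w)


class TestOptimizePrimerSet:
    def test_single_candidate_per_role_is_returned_directly(self):
        cands = {
            "sF": [_mk("GACGATCGATCGATCGATCG", 60, 0.9)],
            "sR": [_mk("CATCGGATCGAACGGATCCA", 60, 0.8, 400, "-")],
        }
        got = optimize_primer_set(cands, seed=0)
        w, _ = set_weight_of({r: c[0] for r, c in cands.items()})
        assert got.set_weight == pytest.approx(w)
        assert got.roles["sF"].sequence == "GACGATCGATCGATCGATCG"

    def test_matches_exhaustive_enumeration_on_small_instances(self):
        rng = np.random.default_rng(14)
        for trial in range(5):
            cands = {}
            for role in ("sF", "sR", "oF_delta", "oR_delta"):
                cands[role] = [
                    _mk(random_dna(rng, 20), float(rng.uniform(55, 65)),
                        float(rng.uniform(0.2, 1.0)), i, role[-1] in "R" and "-" or "+")
                    for i in range(4)
                ]
            sa = optimize_primer_set(
                cands, annealing_params=AnnealingParams(iterations=4000), seed=trial
            )
            ex = exhaustive_primer_set(cands)
            assert sa.set_weight == pytest.approx(ex.set_weight)

    def test_same_seed_reproduces_identical_set(self):
        rng = np.random.default_rng(15)
        cands = {
            role: [_mk(random_dna(rng, 20), float(rng.uniform(55, 65)),
                       float(rng.uniform(0.2, 1.0)), i) for i in range(6)]
            for role in ("sF", "sR", "AmpF", "AmpR")
        }
        a = optimize_primer_set(cands, seed=99)
        b = optimize_primer_set(cands, seed=99)
        assert {r: p.sequence for r, p in a.roles.items()} == {
            r: p.sequence for r, p in b.roles.items()
        }

    def test_duplicate_sequences_across_roles_excluded(self):
        shared = "GACGATCGATCGATCGATCG"
        cands = {
            "sF": [_mk(shared, 60, 1.0)],
            "sR": [_mk(shared, 60, 1.0, 400, "-"), _mk("CATCGGATCGAACGGATCCA", 58, 0.5, 400, "-")],
        }
        got = optimize_primer_set(cands, seed=1)
        assert got.roles["sR"].sequence != shared
        assert got.set_weight > 0

    def test_missing_mandatory_role_raises(self):
        with pytest.raises(PrimerRoleError, match="sR"):
            optimize_primer_set({"sF": [_mk("GACGATCGATCGATCGATCG", 60, 1.0)]}, seed=0)


class TestInsilicoPCR:
    def test_length_arithmetic(self):
        fwd = "GACGATCGATCGATCGATCG"
        rev_site = "ATGGATCGGTACCAGGATCC"  # appears on + strand; reverse primer is its rc
        template = "A" * 100 + fwd + "C" * 80 + rev_site + "A" * 100
        rev = reverse_complement(rev_site)
        # reverse site ends at 100+20+80+20 = 220; forward starts at 100
        assert insilico_pcr(template, fwd, rev) == [120]

    def test_opposite_orientation_gives_no_product(self):
        fwd = "GACGATCGATCGATCGATCG"
        other = "ATGGATCGGTACCAGGATCC"
        template = "A" * 50 + fwd + "C" * 80 + other + "A" * 50
        assert insilico_pcr(template, fwd, other) == []

    def test_size_cap_enforced(self):
        fwd = "GACGATCGATCGATCGATCG"
        rev_site = "ATGGATCGGTACCAGGATCC"
        template = "A" * 10 + fwd + "C" * 300 + rev_site + "A" * 10
        rev = reverse_complement(rev_site)
        assert insilico_pcr(template, fwd, rev, max_amplicon=200) == []

    def test_multiple_planted_sites_agree_with_brute_force(self):
        rng = np.random.default_rng(44)
        fwd = "GACGATCGATCGATCGATCG"
        rev_site = "ATGGATCGGTACCAGGATCC"
        rev = reverse_complement(rev_site)
        parts = [random_dna(rng, 150)]
        for piece in (fwd, rev_site, fwd, rev_site, rev_site):
            parts += [piece, random_dna(rng, int(rng.integers(50, 250)))]
        template = "".join(parts)
        assert insilico_pcr(template, fwd, rev, 5000) == naive_pcr(template, fwd, rev, 5000)

    def test_mismatch_tolerance_requires_exact_3prime(self):
        fwd = "GACGATCGATCGATCGATCG"
        variant = "T" + fwd[1:]  # one 5' mismatch
        rev_site = "ATGGATCGGTACCAGGATCC"
        template = "A" * 30 + variant + "C" * 60 + rev_site + "A" * 30
        rev = reverse_complement(rev_site)
        assert insilico_pcr(template, fwd, rev, mismatch_tolerance=0) == []
        # product spans variant start (30) to reverse-site end (130)
        assert insilico_pcr(template, fwd, rev, mismatch_tolerance=1) == [100]
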