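"""Target scanning, off-target search, QC, expansion, ranking, sweep."""

import math

import numpy as np
import pytest

from tagback import (
    Feature,
    FeatureNotEditableError,
    Genome,
    OffTargetIndex,
    QCThresholds,
    check_arm_polymorphism,
    editability_sweep,
    expand_feature,
    find_offtargets,
    qc_evaluate,
    rank_targets,
    scan_targets,
)
from tagback.fixtures import LANDING_PAD_SITE
from tagback.synth import SyntheticSpec, generate_synthetic_genome

from .conftest import random_dna
from .oracles import naive_offtargets, naive_scan


class TestScanTargets:
    def test_planted_site_found_exactly_once(self, plain_cas9):
        # short A flanks leave no room for spurious spacer windows before the
        # site's internal GG dinucleotides, so the planted site is the only hit
        seq = "A" * 5 + LANDING_PAD_SITE + "A" * 5
        g = Genome({"c": seq})
        hits = scan_targets(g, plain_cas9, ("c", 0, len(seq)))
        assert len(hits) == 1
        t = hits[0]
        assert (t.start, t.strand, t.spacer, t.pam) == (
            5, "+", LANDING_PAD_SITE[:20], LANDING_PAD_SITE[20:]
        )

    def test_all_a_region_has_no_targets(self, plain_cas9):
        assert scan_targets(Genome({"c": "A" * 300}), plain_cas9) == []

    def test_overlap_by_one_bp_counts(self, plain_cas9):
        seq = "A" * 100 + LANDING_PAD_SITE + "A" * 100
        g = Genome({"c": seq})
        # region touching only the last base of the 23 bp window
        assert len(scan_targets(g, plain_cas9, ("c", 122, 150))) == 1
        assert scan_targets(g, plain_cas9, ("c", 123, 150)) == []

    def test_agrees_with_naive_oracle_on_random_sequence(self, plain_cas9):
        rng = np.random.default_rng(17)
        seq = random_dna(rng, 10000)
        got = sorted((t.start, t.strand, t.spacer, t.pam)
                     for t in scan_targets(Genome({"c": seq}), plain_cas9))
        assert got == naive_scan(seq, "N" * 20, "NGG")

    def test_cut_position_three_nt_from_pam(self, cas9):
        seq = "A" * 50 + LANDING_PAD_SITE + "A" * 50
        t = next(
            t for t in scan_targets(Genome({"c": seq}), cas9)
            if t.start == 50 and t.strand == "+"
        )
        assert t.cut_position == 50 + 20 - 3  # between spacer positions 17|18


class TestFindOfftargets:
    def test_on_target_only_genome_gives_no_hits(self, plain_cas9):
        seq = "A" * 60 + LANDING_PAD_SITE + "A" * 60
        g = Genome({"c": seq})
        hits = find_offtargets(g, LANDING_PAD_SITE[:20], plain_cas9, 5,
                               exclude_site=("c", 60, "+"))
        assert hits == []

    def test_planted_two_mismatch_copy_recovered(self, plain_cas9):
        spacer = LANDING_PAD_SITE[:20]
        mutated = list(spacer)
        mutated[4] = "A" if mutated[4] != "A" else "C"   # spacer position 5
        mutated[12] = "A" if mutated[12] != "A" else "C"  # spacer position 13
        decoy = "".join(mutated) + "AGG"
        seq = "A" * 50 + LANDING_PAD_SITE + "A" * 50 + decoy + "A" * 50
        g = Genome({"c": seq})
        hits = find_offtargets(g, spacer, plain_cas9, 5, exclude_site=("c", 50, "+"))
        assert len(hits) == 1
        assert hits[0].n_mismatches == 2
        assert hits[0].mismatch_positions == (5, 13)

    def test_agrees_with_exhaustive_oracle(self, plain_cas9):
        rng = np.random.default_rng(23)
        contigs = {"c1": random_dna(rng, 2000), "c2": random_dna(rng, 1000)}
        g = Genome(contigs)
        spacer = random_dna(rng, 20)
        got = sorted(
            (h.contig, h.position, h.strand, h.mismatch_positions)
            for h in find_offtargets(g, spacer, plain_cas9, 3)
        )
        assert got == naive_offtargets(contigs, spacer, "NGG", 3)

    def test_five_prime_pam_positions_are_pam_distal_from_three_prime_end(self):
        from tagback import parse_motif

        motif = parse_motif("TTTA<NNNNNNNNNN")
        spacer = "ACGTACGTAC"
        site = "TTTA" + "ACGTACGTAG"  # mismatch at spacer 3' end = position 1
        g = Genome({"c": "C" * 30 + site + "C" * 30})
        (hit,) = find_offtargets(g, spacer, motif, 2)
        assert hit.mismatch_positions == (1,)


class TestQC:
    def _target(self, spacer, plain_cas9):
        seq = "A" * 30 + spacer + "TGG" + "A" * 30
        g = Genome({"c": seq})
        t = next(
            t for t in scan_targets(g, plain_cas9, ("c", 30, 30 + 23))
            if t.start == 30 and t.strand == "+"
        )
        return t, g

    def test_polyt_failure_reason(self, plain_cas9, thresholds):
        t, g = self._target("GTTTTTCGACGACGACGCAG", plain_cas9)
        t = qc_evaluate(t, [], thresholds)
        assert not t.passes_qc and "polyT" in t.failure_reasons

    def test_gc_failure_reason(self, plain_cas9, thresholds):
        t, _ = self._target("G" * 10 + "C" * 10, plain_cas9)
        t = qc_evaluate(t, [], thresholds)
        assert not t.passes_qc and "GC" in t.failure_reasons

    def test_clean_spacer_passes(self, plain_cas9, thresholds):
        t, _ = self._target("GACGATCGATCGATCGATCA", plain_cas9)
        t = qc_evaluate(t, [], thresholds)
        assert t.passes_qc and t.metrics["errors"] == math.inf
        assert t.metrics["offtarget_aggregate"] == 100.0

    def test_near_identical_offtarget_fails_uniqueness(self, plain_cas9, thresholds):
        from tagback import OffTargetHit

        t, _ = self._target("GACGATCGATCGATCGATCA", plain_cas9)
        hit = OffTargetHit("c", 500, "+", (7,))
        t = qc_evaluate(t, [hit], thresholds)
        assert "errors" in t.failure_reasons
        assert t.metrics["errors"] == 1


class TestExpandFeature:
    def test_passing_target_inside_leaves_bounds_unchanged(self, plain_cas9):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 400) + "GACGATCGATCGATCGATCATGG" + random_dna(rng, 400)
        g = Genome({"c": seq})
        feat = Feature("c", 395, 430, name="f")
        out = expand_feature(g, feat, plain_cas9)
        assert (out.expanded_start, out.expanded_end) == (395, 430)

    def test_expansion_reaches_upstream_target(self, plain_cas9):
        # no NGG anywhere except a clean site planted 172 bp upstream
        site = "GACGATCGATCGATCGATCATGG"
        pos = 300
        feat_pos = pos + len(site) + 172
        seq = "A" * pos + site + "A" * 172 + "TTAAAGTTT" + "A" * 300
        g = Genome({"c": seq})
        feat = Feature("c", feat_pos, feat_pos + 9, name="wor1")
        out = expand_feature(g, feat, plain_cas9)
        assert out.expanded_start <= pos
        assert out.expanded_end - out.expanded_start <= 4096

    def test_no_target_within_cap_is_not_editable(self, plain_cas9):
        g = Genome({"c": "A" * 9000})
        feat = Feature("c", 4500, 4509, name="f")
        with pytest.raises(FeatureNotEditableError):
            expand_feature(g, feat, plain_cas9)

    def test_relaxing_thresholds_never_widens_expansion(self, plain_cas9):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 3000)
        g = Genome({"c": seq})
        feat = Feature("c", 1500, 1510, name="f")
        strict = QCThresholds()
        relaxed = QCThresholds(polyt_max=20, gc_min=0.1, gc_max=99.9, ontarget_min=0)
        try:
            w_strict = expand_feature(g, feat, plain_cas9, strict).expanded_length
        except FeatureNotEditableError:
            w_strict = math.inf
        w_relaxed = expand_feature(g, feat, plain_cas9, relaxed).expanded_length
        assert w_relaxed <= w_strict


class TestArmPolymorphism:
    def test_identical_arms_pass(self):
        assert check_arm_polymorphism("ACGT" * 10, "ACGT" * 10)

    def test_ten_percent_divergence_fails_default(self):
        a = "A" * 50
        b = "C" * 5 + "A" * 45
        assert not check_arm_polymorphism(a, b)

    def test_two_in_fifty_is_within_default_cap(self):
        a = "ACGT" * 12 + "AC"
        b = "TCGT" * 1 + a[4:48] + "AT"  # 2 mismatches over 50
        mism = sum(x != y for x, y in zip(a, b))
        assert mism == 2
        assert check_arm_polymorphism(a, b)  # 2/50 = 0.04 <= 0.05

    def test_length_mismatch_flagged_as_indel(self):
        with pytest.raises(ValueError, match="indel"):
            check_arm_polymorphism("ACGT", "ACGTA")


class TestRankTargets:
    def test_passing_before_failing_and_deterministic(self, plain_cas9, thresholds):
        rng = np.random.default_rng(29)
        seq = random_dna(rng, 4000)
        g = Genome({"c": seq})
        index = OffTargetIndex(g, plain_cas9)
        cands = [
            qc_evaluate(t, index.query(t.spacer, 5, t.site), thresholds)
            for t in scan_targets(g, plain_cas9)
        ]
        ranked = rank_targets(cands)
        flags = [t.passes_qc for t in ranked]
        assert flags == sorted(flags, reverse=True)
        # permutation of the input leaves the output identical
        perm = [cands[i] for i in rng.permutation(len(cands))]
        assert [t.site for t in rank_targets(perm)] == [t.site for t in ranked]


class TestEditabilitySweep:
    def test_indirect_dominates_direct_and_direct_monotone(self, cas9):
        sg = generate_synthetic_genome(SyntheticSpec(length=30000, seed=8))
        df = editability_sweep(sg.genome, 50, motif=cas9, seed=2)
        assert (df.indirect_prop >= df.direct_prop).all()
        assert (df.direct_prop.diff().dropna() >= 0).all()

    def test_motif_matching_nothing_gives_zero_everywhere(self):
        from tagback import parse_motif

        g = Genome({"c": "A" * 5000})
        df = editability_sweep(g, 20, motif=parse_motif("N{20}>NGG"), seed=0)
        assert (df.direct_prop == 0).all() and (df.indirect_prop == 0).all()

    def test_full_contig_feature_with_passing_target_is_direct(self, plain_cas9):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 1200) + "GACGATCGATCGATCGATCATGG" + random_dna(rng, 1200)
        g = Genome({"c": seq})
        df = editability_sweep(
            g, 10, feature_sizes=[len(seq)], motif=plain_cas9, seed=3
        )
        assert df.direct_prop.iloc[0] == 1.0
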