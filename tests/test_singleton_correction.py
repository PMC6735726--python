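"""Cross-strand rescue of singletons."""

import numpy as np
import pytest

from duplexsc.bamio import read_pairs
from duplexsc.families import duplex_transform, family_key, group_pairs
from duplexsc.sscs import ConsensusConfig, collapse_family, route_families, singleton_pair
from duplexsc.singleton_correction import (
    correct_by_singleton,
    correct_by_sscs,
    run_singleton_correction,
)
from conftest import make_paired_read


def _complementary_singletons(**kwargs):
    """A plus-strand singleton and its complementary minus-strand singleton."""
    plus = make_paired_read(qname="p|ACGT", barcode="ACGT", **kwargs)
    minus = make_paired_read(
        qname="m|GTAC", barcode="GTAC", reverse1=True, **kwargs
    )
    # the minus-strand R1 covers the plus-strand R2's segment and vice versa
    minus.pos1, minus.pos2 = plus.pos2, plus.pos1
    minus.seq1, minus.seq2 = plus.seq2.copy(), plus.seq1.copy()
    minus.qual1, minus.qual2 = plus.qual2.copy(), plus.qual1.copy()
    s1 = singleton_pair(_fam(plus))
    s2 = singleton_pair(_fam(minus))
    assert family_key(minus) == duplex_transform(family_key(plus))
    return s1, s2


def _fam(pair):
    from duplexsc.families import ReadFamily

    return ReadFamily(key=family_key(pair), members=[pair])


class TestCorrectBySingleton:
    def test_identical_complements_pass_through(self):
        s1, s2 = _complementary_singletons()
        c1, c2 = correct_by_singleton(s1, s2)
        assert c1.r1.sequence() == s1.r1.sequence()
        assert c2.r1.sequence() == s2.r1.sequence()
        assert c1.provenance == c2.provenance == "SC_by_singleton"

    def test_discordant_position_becomes_n_in_both_outputs(self):
        s1, s2 = _complementary_singletons()
        s1.r1.seq[7] = ord("G")  # error on the plus strand only
        c1, c2 = correct_by_singleton(s1, s2)
        assert c1.r1.sequence()[7] == "N" and c1.r1.qual[7] == 0
        assert c2.r2.sequence()[7] == "N"
        assert c1.r1.sequence()[8] == "A"  # neighbours untouched

    def test_independent_errors_at_different_positions_both_masked(self):
        s1, s2 = _complementary_singletons()
        s1.r1.seq[3] = ord("G")
        s2.r2.seq[9] = ord("T")
        c1, c2 = correct_by_singleton(s1, s2)
        for c in (c1.r1, c2.r2):
            assert c.sequence()[3] == "N" and c.sequence()[9] == "N"

    def test_same_error_on_both_strands_survives(self):
        # the known residual class: concordant wrongness is indistinguishable
        s1, s2 = _complementary_singletons()
        s1.r1.seq[3] = ord("G")
        s2.r2.seq[3] = ord("G")
        c1, _ = correct_by_singleton(s1, s2)
        assert c1.r1.sequence()[3] == "G"

    def test_sub_q30_base_on_either_side_masks_position(self):
        s1, s2 = _complementary_singletons()
        s2.r2.qual[4] = 29
        c1, c2 = correct_by_singleton(s1, s2)
        assert c1.r1.sequence()[4] == "N"
        assert c2.r2.sequence()[4] == "N"

    def test_symmetry_under_argument_swap(self):
        s1, s2 = _complementary_singletons()
        s1.r1.seq[5] = ord("T")
        a1, a2 = correct_by_singleton(s1, s2)
        b2, b1 = correct_by_singleton(s2, s1)
        assert a1.r1.sequence() == b1.r1.sequence()
        assert a2.r1.sequence() == b2.r1.sequence()

    def test_same_strand_pair_is_hard_error(self):
        s1, _ = _complementary_singletons()
        with pytest.raises(ValueError, match="complementary"):
            correct_by_singleton(s1, s1)


class TestCorrectBySSCS:
    def test_error_masked_against_clean_sscs(self):
        s1, s2 = _complementary_singletons()
        dup = make_paired_read(qname="d|GTAC", barcode="GTAC", reverse1=True)
        dup.pos1, dup.pos2 = s2.key.pos1, s2.key.pos2
        dup.seq1, dup.seq2 = s2.r1.seq.copy(), s2.r2.seq.copy()
        other = make_paired_read(qname="e|GTAC", barcode="GTAC", reverse1=True)
        other.pos1, other.pos2 = s2.key.pos1, s2.key.pos2
        other.seq1, other.seq2 = s2.r1.seq.copy(), s2.r2.seq.copy()
        from duplexsc.families import ReadFamily

        sscs = collapse_family(ReadFamily(key=s2.key, members=[dup, other]))
        singleton = s1
        singleton.r1.seq[11] = ord("G")
        corrected = correct_by_sscs(singleton, sscs)
        assert corrected.provenance == "SC_by_SSCS"
        assert corrected.family_size == 1
        assert corrected.r1.sequence()[11] == "N"
        assert corrected.r1.sequence()[12] == "A"

    def test_mismatched_duplex_keys_hard_error(self):
        s1, _ = _complementary_singletons()
        other = singleton_pair(_fam(make_paired_read(qname="z|TTTT", barcode="TTTT")))
        with pytest.raises(ValueError):
            correct_by_sscs(s1, other)


class TestRunSingletonCorrection:
    def test_stream_sizes_match_strand_pattern_truth(self, sim_factory):
        """(1,>=2) -> by-SSCS, (1,1) -> by-singleton, (1,0) -> uncorrected."""
        res, _ = sim_factory(
            "patterns", n_molecules=600, per_strand_reads="poisson:1.0", seed=33
        )
        pairs, _ = read_pairs(res.bam)
        collapsible, singles = route_families(group_pairs(pairs))
        sscs = [collapse_family(f) for f in collapsible]
        singletons = [singleton_pair(f) for f in singles]
        out = run_singleton_correction(singletons, sscs)

        t = res.truth
        n1 = np.minimum(t["n_plus"], t["n_minus"])
        n2 = np.maximum(t["n_plus"], t["n_minus"])
        expect_by_sscs = int(((n1 == 1) & (n2 >= 2)).sum())
        expect_by_singleton = 2 * int(((n1 == 1) & (n2 == 1)).sum())
        expect_uncorrected = int(((n1 == 0) & (n2 == 1)).sum())
        assert len(out.by_sscs) == expect_by_sscs
        assert len(out.by_singleton) == expect_by_singleton
        assert len(out.uncorrected) == expect_uncorrected
        # conservation: every singleton lands in exactly one stream
        assert (
            len(out.by_sscs) + len(out.by_singleton) + len(out.uncorrected)
            == len(singletons)
        )

    def test_priority_sscs_over_singleton(self):
        """A singleton whose complement has an SSCS is corrected by it, and
        the complementary singleton situation cannot then arise (grouping
        makes strand streams unique), so priority reduces to: by-SSCS wins
        whenever a complementary SSCS exists."""
        s1, s2 = _complementary_singletons()
        dup_a = make_paired_read(qname="d1|GTAC", barcode="GTAC", reverse1=True)
        dup_b = make_paired_read(qname="d2|GTAC", barcode="GTAC", reverse1=True)
        for d in (dup_a, dup_b):
            d.pos1, d.pos2 = s2.key.pos1, s2.key.pos2
            d.seq1, d.seq2 = s2.r1.seq.copy(), s2.r2.seq.copy()
        from duplexsc.families import ReadFamily

        sscs = collapse_family(ReadFamily(key=s2.key, members=[dup_a, dup_b]))
        out = run_singleton_correction([s1], [sscs])
        assert len(out.by_sscs) == 1 and not out.by_singleton and not out.uncorrected

    def test_lone_singleton_stays_uncorrected(self):
        s1, _ = _complementary_singletons()
        out = run_singleton_correction([s1], [])
        assert out.uncorrected == [s1]
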