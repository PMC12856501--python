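"""Alignment scoring, variant calling round trips, zygosity rules, and
cohort arithmetic."""

import itertools
import random

import pytest

from uorfkit.edits import Edit, EditKind, apply_edits
from uorfkit.genotype import (
    GenotypeError,
    Scoring,
    align_pair,
    call_variants,
    classify_zygosity,
    genotype_clone,
    round_half_up,
    signature,
    summarize_cohort,
)

from conftest import brute_align_score


class TestAlignPair:
    def test_identical_sequences_score(self):
        seq = "".join(random.Random(0).choice("ACGT") for _ in range(50))
        aln = align_pair(seq, seq)
        assert aln.score == 100.0
        assert "-" not in aln.ref_aligned + aln.query_aligned

    def test_single_deletion_run(self):
        ref = "".join(random.Random(1).choice("ACGT") for _ in range(60))
        query = ref[:20] + ref[23:]
        aln = align_pair(ref, query)
        edits = call_variants(aln)
        assert len(edits) == 1
        assert edits[0].kind is EditKind.DEL and edits[0].del_len == 3

    def test_gap_removal_reproduces_inputs(self):
        ref = "ACGTACGTAA"
        query = "ACGTCGTA"
        aln = align_pair(ref, query)
        assert aln.ref_aligned.replace("-", "") == ref
        assert aln.query_aligned.replace("-", "") == query

    def test_empty_sequence_rejected(self):
        with pytest.raises(GenotypeError):
            align_pair("", "ACGT")

    def test_length_cap(self):
        with pytest.raises(GenotypeError):
            align_pair("A" * 30, "A" * 10, max_len=20)

    @pytest.mark.parametrize("seed", range(60))
    def test_score_matches_exhaustive_oracle_short_pairs(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
        assert align_pair(a, b).score == brute_align_score(a, b)

    def test_score_oracle_on_all_length2_pairs(self):
        for a, b in itertools.product(["AA", "AC", "GT", "TT"], repeat=2):
            assert align_pair(a, b).score == brute_align_score(a, b)


class TestCallVariants:
    def test_identical_alignment_empty(self):
        seq = "ACGTACGT"
        assert call_variants(align_pair(seq, seq)) == []

    def test_deletion_left_aligned_in_repeat(self):
        ref = "GGGACACTTT"
        query = "GGGACTTT"  # drop one "AC" unit: leftmost placement is pos 3
        edits = call_variants(align_pair(ref, query))
        assert len(edits) == 1
        e = edits[0]
        assert e.kind is EditKind.DEL and e.del_len == 2 and e.pos == 3

    def test_insertion_left_aligned_in_repeat(self):
        ref = "GGGACTTT"
        query = "GGGACACTTT"
        edits = call_variants(align_pair(ref, query))
        assert len(edits) == 1
        e = edits[0]
        assert e.kind is EditKind.INS and e.pos == 3 and e.alt_seq == "AC"

    def test_adjacent_substitutions_merge(self):
        ref = "AAAACCAAAA"
        query = "AAAATTAAAA"
        edits = call_variants(align_pair(ref, query))
        assert [e.kind for e in edits] == [EditKind.SUB]
        assert edits[0].alt_seq == "TT"

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_apply_call_identity(self, seed):
        """apply(ref, call(align(ref, allele))) reproduces the allele."""
        rng = random.Random(seed)
        ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 160)))
        allele = _mutate(rng, ref)
        edits = call_variants(align_pair(ref, allele))
        assert apply_edits(ref, edits).seq == allele


def _mutate(rng, ref):
    """Simulated allele: a few separated dels/ins/subs."""
    seq = list(ref)
    n_events = rng.randint(0, 3)
    positions = sorted(rng.sample(range(5, len(ref) - 15), n_events) if n_events else [])
    offset = 0
    for p in positions:
        p += offset
        kind = rng.choice(["del", "ins", "sub"])
        size = rng.randint(1, 8)
        if kind == "del":
            del seq[p : p + size]
            offset -= min(size, max(0, len(seq) - p))
        elif kind == "ins":
            ins = [rng.choice("ACGT") for _ in range(size)]
            seq[p:p] = ins
            offset += size
        else:
            for k in range(p, min(p + size, len(seq))):
                seq[k] = rng.choice([b for b in "ACGT" if b != seq[k]])
    return "".join(seq)


class TestZygosity:
    def sig(self, *edits):
        return signature(list(edits))

    def test_homozygous(self):
        d = self.sig(Edit(EditKind.DEL, 10, del_len=3))
        call = classify_zygosity("L1", [d] * 6)
        assert call.category == "HOMOZYGOUS"
        assert call.hemizygous_possible

    def test_heterozygous_wt_plus_edited(self):
        d = self.sig(Edit(EditKind.DEL, 10, del_len=3))
        call = classify_zygosity("L2", [()] * 3 + [d] * 3)
        assert call.category == "HETEROZYGOUS"

    def test_chimeric_three_signatures(self):
        sigs = [
            self.sig(Edit(EditKind.DEL, 5, del_len=2)),
            self.sig(Edit(EditKind.DEL, 20, del_len=4)),
            self.sig(Edit(EditKind.SUB, 30, alt_seq="T")),
        ]
        call = classify_zygosity("L3", [s for s in sigs for _ in range(3)])
        assert call.category == "CHIMERIC"

    def test_wild_type(self):
        call = classify_zygosity("L4", [()] * 5)
        assert call.category == "WILD_TYPE"
        assert not call.edited

    def test_low_support_signatures_discarded(self):
        d = self.sig(Edit(EditKind.DEL, 10, del_len=3))
        noise = self.sig(Edit(EditKind.SUB, 50, alt_seq="A"))
        call = classify_zygosity("L5", [d] * 5 + [noise])
        assert call.category == "HOMOZYGOUS"
        assert call.n_discarded == 1

    def test_all_discarded_is_error(self):
        sigs = [self.sig(Edit(EditKind.SUB, i, alt_seq="A")) for i in range(4)]
        with pytest.raises(GenotypeError, match="insufficient clone support"):
            classify_zygosity("L6", sigs)

    def test_fewer_than_two_clones_rejected(self):
        with pytest.raises(GenotypeError):
            classify_zygosity("L7", [()])


class TestCohortSummary:
    def _calls(self, hom=0, het=0, chi=0, wt=0):
        from uorfkit.genotype import ZygosityCall

        out = []
        i = 0
        for cat, n in (("HOMOZYGOUS", hom), ("HETEROZYGOUS", het),
                       ("CHIMERIC", chi), ("WILD_TYPE", wt)):
            for _ in range(n):
                out.append(ZygosityCall(f"l{i}", cat, (((), 2),), 2, 0))
                i += 1
        return out

    def test_study_cohort_arithmetic(self):
        calls = self._calls(hom=6, het=13, chi=6, wt=5)
        s = summarize_cohort(93, 30, calls)
        assert s.transformation_efficiency_pct == 32.26
        assert s.editing_efficiency_pct == 83.33
        assert s.heterozygous_pct == 43.33
        assert s.chimeric_pct == 20.0
        assert s.homozygous_pct == 20.0
        assert s.n_edited == 25

    def test_category_percentages_sum_to_editing_efficiency(self):
        calls = self._calls(hom=6, het=13, chi=6, wt=5)
        s = summarize_cohort(93, 30, calls)
        total = s.homozygous_pct + s.heterozygous_pct + s.chimeric_pct
        assert total == pytest.approx(s.editing_efficiency_pct, abs=0.02)

    def test_zero_transgenic_undefined_editing(self):
        s = summarize_cohort(10, 0, [])
        assert s.transformation_efficiency_pct == 0.0
        assert s.editing_efficiency_pct is None

    def test_invalid_counts(self):
        with pytest.raises(GenotypeError):
            summarize_cohort(5, 10, [])


def test_round_half_up():
    assert round_half_up(32.258064, 2) == 32.26
    assert round_half_up(0.005, 2) == 0.01
    assert round_half_up(83.333333, 2) == 83.33
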