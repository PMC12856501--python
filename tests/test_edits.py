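"""Edit application, coordinate mapping, and uORF landscape deltas."""

import random

import pytest

from uorfkit.annotate import LeaderContext, UOrfType, annotate_leader
from uorfkit.edits import (
    Edit,
    EditError,
    EditKind,
    apply_edits,
    diff_annotations,
    predict_edit_outcome,
)
from uorfkit.simulate import EditPattern, ck_spec, plant_leader, simulate_edit_pattern

from conftest import random_context


def DEL(pos, n):
    return Edit(EditKind.DEL, pos, del_len=n)


def INS(pos, s):
    return Edit(EditKind.INS, pos, alt_seq=s)


def SUB(pos, s):
    return Edit(EditKind.SUB, pos, alt_seq=s)


class TestApplyEdits:
    def test_simple_deletion(self):
        a = apply_edits("AAACCCGGG", [DEL(3, 3)])
        assert a.seq == "AAAGGG"
        assert a.net_length_change == -3

    def test_del_plus_ins_net_change(self):
        ref = "".join(random.Random(0).choice("ACGT") for _ in range(200))
        a = apply_edits(ref, [DEL(20, 29), INS(100, "TTTT")])
        assert a.net_length_change == -25
        assert len(a.seq) == 175

    def test_two_deletions_net_change(self):
        ref = "A" * 200
        a = apply_edits(ref, [DEL(10, 64), DEL(150, 8)])
        assert a.net_length_change == -72

    def test_substitution_in_place(self):
        a = apply_edits("AAAAAA", [SUB(2, "GG")])
        assert a.seq == "AAGGAA"
        assert a.net_length_change == 0

    def test_overlapping_edits_rejected(self):
        with pytest.raises(EditError, match="overlap"):
            apply_edits("AAAAAAAA", [DEL(2, 3), SUB(4, "T")])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(EditError, match="outside"):
            apply_edits("AAAA", [DEL(2, 5)])

    def test_coord_map_strictly_increasing_and_consistent(self):
        rng = random.Random(5)
        for _ in range(50):
            ref = "".join(rng.choice("ACGT") for _ in range(80))
            edits = _random_edits(rng, len(ref))
            a = apply_edits(ref, edits)
            items = sorted(a.coord_map.items())
            assert all(v1 < v2 for (_, v1), (_, v2) in zip(items, items[1:]))
            deleted = set()
            subbed = set()
            for e in edits:
                if e.kind is EditKind.DEL:
                    deleted.update(range(*e.span))
                elif e.kind is EditKind.SUB:
                    subbed.update(range(*e.span))
            for p, q in items:
                assert p not in deleted
                if p not in subbed:
                    assert a.seq[q] == ref[p]

    def test_ins_and_del_at_same_position(self):
        # simultaneous semantics: insertion lands before the deleted block
        a = apply_edits("AAACCC", [DEL(3, 3), INS(3, "GG")])
        assert a.seq == "AAAGG"


def _random_edits(rng, n, max_edits=4):
    edits = []
    taken = []
    for _ in range(rng.randint(0, max_edits)):
        kind = rng.choice(list(EditKind))
        pos = rng.randint(0, n - 6)
        size = rng.randint(1, 5)
        span = (pos, pos + size if kind is not EditKind.INS else pos)
        if any(s < span[1] + 1 and span[0] < e + 1 for s, e in taken):
            continue
        taken.append(span)
        if kind is EditKind.DEL:
            edits.append(DEL(pos, size))
        elif kind is EditKind.INS:
            edits.append(INS(pos, "".join(rng.choice("ACGT") for _ in range(size))))
        else:
            edits.append(SUB(pos, "".join(rng.choice("ACGT") for _ in range(size))))
    return edits


class TestComposition:
    @pytest.mark.parametrize("seed", range(20))
    def test_sequential_equals_merged(self, seed):
        """Applying E1 then E2 (E2 re-expressed in edited coordinates) gives
        the same sequence as applying the merged set in reference space."""
        rng = random.Random(seed)
        ref = "".join(rng.choice("ACGT") for _ in range(150))
        e1 = _random_edits(rng, 60)
        e2 = [
            Edit(e.kind, e.pos + 80, e.del_len, e.alt_seq)
            for e in _random_edits(rng, 60)
        ]
        merged = apply_edits(ref, e1 + e2)
        step1 = apply_edits(ref, e1)
        shifted = [
            Edit(e.kind, step1.coord_map[e.pos], e.del_len, e.alt_seq) for e in e2
        ]
        step2 = apply_edits(step1.seq, shifted)
        assert step2.seq == merged.seq


class TestPredictAndDiff:
    def test_empty_edit_set_is_identity(self, ck_truth):
        _, after, delta = predict_edit_outcome(ck_truth.context, [])
        assert delta.total_before == delta.total_after == 5
        assert delta.percent_change_total == 0.0
        assert delta.type_transitions == ()
        assert delta.n_destroyed == delta.n_created == 0

    def test_disrupting_two_of_five_uatgs(self, ck_truth):
        edits = simulate_edit_pattern(ck_truth, EditPattern("disrupt_k_uatg", k=2), seed=11)
        _, _, delta = predict_edit_outcome(ck_truth.context, edits)
        assert (delta.total_before, delta.total_after) == (5, 3)
        assert delta.percent_change_total == -40.0

    def test_type3_acquisition(self):
        from uorfkit.simulate import PlantSpec, PlantedUOrf

        spec = PlantSpec(
            leader_len=192,
            planted=(
                PlantedUOrf(UOrfType.TYPE1, 57),
                PlantedUOrf(UOrfType.TYPE1, 15),
                PlantedUOrf(UOrfType.TYPE1, 30, uatg_pos=90),  # in mATG frame
                PlantedUOrf(UOrfType.TYPE1, 54),
                PlantedUOrf(UOrfType.TYPE1, 84),
            ),
            seed=11,
        )
        truth = plant_leader(spec)
        edits = simulate_edit_pattern(truth, EditPattern("convert_to_type3", k=2), seed=1)
        _, after, delta = predict_edit_outcome(truth.context, edits)
        assert delta.n_destroyed == 2
        assert delta.counts_after[UOrfType.TYPE3] >= 1
        assert any(t[2] is UOrfType.TYPE3 for t in delta.type_transitions)

    def test_surviving_substituted_atg_counts_as_surviving(self):
        # SUB rewrites the uATG's first base to the same letter: still ATG
        ctx = LeaderContext("t", "CCATGTAACC", "ATGGGGTGA")
        _, _, delta = predict_edit_outcome(ctx, [SUB(2, "ATG")])
        assert delta.n_destroyed == 0 and delta.n_created == 0

    def test_substitution_destroying_uatg(self):
        ctx = LeaderContext("t", "CCATGTAACC", "ATGGGGTGA")
        _, _, delta = predict_edit_outcome(ctx, [SUB(2, "AAA")])
        assert delta.n_destroyed == 1
        assert delta.total_after == 0

    def test_edit_in_cds_requires_override(self):
        ctx = LeaderContext("t", "CCATGTAACC", "ATGGGGTGA")
        with pytest.raises(EditError, match="CDS"):
            predict_edit_outcome(ctx, [SUB(12, "C")])

    def test_destroying_matg_is_integrity_error(self):
        ctx = LeaderContext("t", "CCATGTAACC", "ATGGGGTGA")
        with pytest.raises(EditError):
            predict_edit_outcome(ctx, [DEL(8, 4)], allow_cds_edits=True)

    @pytest.mark.parametrize("seed", range(15))
    def test_conservation_of_uatg_counts(self, seed):
        """destroyed - created == n_ref_uATGs - n_edited_uATGs."""
        rng = random.Random(seed)
        ctx = random_context(rng, max_leader=200)
        edits = [e for e in _random_edits(rng, max(6, ctx.matg_pos - 6))]
        try:
            _, after, delta = predict_edit_outcome(ctx, edits)
        except EditError:
            return
        before = annotate_leader(ctx)
        assert delta.n_destroyed - delta.n_created == len(before.uorfs) - len(after.uorfs)

    def test_identity_diff_zero(self, ck_truth):
        ann = annotate_leader(ck_truth.context)
        allele = apply_edits(ck_truth.context.transcript_seq, [])
        d = diff_annotations(ann, ann, allele)
        assert d.n_destroyed == d.n_created == 0
        assert d.percent_change_total == 0.0

    def test_type_shift_keeps_total(self, ck_truth):
        """A frameshift inside a uORF body trades a Type-1 for a Type-2
        while keeping the total count unchanged."""
        edits = simulate_edit_pattern(ck_truth, EditPattern("convert_to_type2"), seed=2)
        _, _, d = predict_edit_outcome(ck_truth.context, edits)
        assert d.total_before == d.total_after == 5
        assert d.counts_after[UOrfType.TYPE1] == d.counts_before[UOrfType.TYPE1] - 1
        assert d.counts_after[UOrfType.TYPE2] == 1
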