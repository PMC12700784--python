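import random

import pytest
from hypothesis import given, settings, strategies as st

from smrna.array_design import (
    DesignError,
    Fragment,
    TargetTranscript,
    assemble_array,
    plan_fragments,
    split_arrays,
    tile_spacers,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_oracle(seq: str) -> str:
    """Independent string-level reverse complement."""
    return "".join(COMPLEMENT[base] for base in reversed(seq))


def random_seq(n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def transcript(n: int, seed: int = 0) -> TargetTranscript:
    return TargetTranscript("tx", random_seq(n, seed), 0, n)


class TestTiling:
    def test_long_utr_capped_at_default_budget(self):
        spacers = tile_spacers(transcript(1800))
        assert len(spacers) == 48

    def test_exact_two_windows(self):
        spacers = tile_spacers(transcript(72))
        assert len(spacers) == 2
        assert (spacers[0].window_start, spacers[0].window_end) == (0, 36)
        assert (spacers[1].window_start, spacers[1].window_end) == (36, 72)

    def test_spacer_is_reverse_complement_of_window(self):
        tx = transcript(720, seed=3)
        for sp in tile_spacers(tx):
            window = tx.sequence[sp.window_start : sp.window_end]
            assert sp.spacer == revcomp_oracle(window)

    def test_short_utr_rejected(self):
        with pytest.raises(DesignError):
            tile_spacers(transcript(20))

    def test_ambiguous_window_skipped_with_warning(self):
        seq = random_seq(36) + "N" * 36 + random_seq(36, seed=1)
        tx = TargetTranscript("tx", seq, 0, len(seq))
        with pytest.warns(UserWarning):
            spacers = tile_spacers(tx)
        assert len(spacers) == 2
        assert [sp.window_start for sp in spacers] == [0, 72]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        utr_len=st.integers(40, 600),
        spacer_len=st.integers(10, 40),
        gap=st.integers(0, 10),
        cap=st.integers(1, 50),
    )
    def test_windows_tile_without_overlap_inside_utr(
        self, utr_len, spacer_len, gap, cap
    ):
        if utr_len < spacer_len:
            utr_len = spacer_len
        tx = transcript(utr_len, seed=utr_len)
        spacers = tile_spacers(tx, spacer_len, gap, cap)
        assert 1 <= len(spacers) <= cap
        prev_end = -1
        for sp in spacers:
            assert sp.window_end - sp.window_start == spacer_len
            assert sp.window_start > prev_end or prev_end == -1
            assert 0 <= sp.window_start < sp.window_end <= utr_len
            prev_end = sp.window_end - 1
            assert sp.spacer == revcomp_oracle(
                tx.sequence[sp.window_start : sp.window_end]
            )


class TestSplitting:
    def test_even_split_of_full_design(self):
        spacers = tile_spacers(transcript(1800))
        parts = split_arrays(spacers, 2)
        assert [len(p) for p in parts] == [24, 24]

    @pytest.mark.parametrize("n,k,expected", [
        (7, 2, [4, 3]), (5, 5, [1, 1, 1, 1, 1]), (10, 3, [4, 3, 3]),
    ])
    def test_near_even_contiguous_split(self, n, k, expected):
        spacers = tile_spacers(transcript(36 * n), max_spacers=n)
        parts = split_arrays(spacers, k)
        assert [len(p) for p in parts] == expected
        flat = [sp.index for part in parts for sp in part]
        assert flat == list(range(n))  # contiguous and order-preserving

    def test_too_many_arrays_rejected(self):
        with pytest.raises(DesignError):
            split_arrays(tile_spacers(transcript(72)), 3)


class TestAssembly:
    def test_length_formula(self):
        spacers = tile_spacers(transcript(1800))[:24]
        array = assemble_array(spacers, "G" * 36, "A" * 100)
        assert len(array.sequence) == 100 + 25 * 36 + 24 * 36 == 1864

    def test_single_spacer_layout(self):
        array = assemble_array(["TTTT"], repeat_seq="GG", signal_seq="AAA")
        assert array.sequence == "AAA" + "GG" + "TTTT" + "GG"

    def test_round_trip_split_on_repeat(self):
        spacers = tile_spacers(transcript(720, seed=5))
        repeat = "GTTGCAACGGATCGAGCTGTGATGTTAGGCATCGAA"  # synthetic repeat
        array = assemble_array(spacers, repeat, "ACGTACGT")
        body = array.sequence[len("ACGTACGT"):]
        parts = body.split(repeat)
        assert parts[0] == "" and parts[-1] == ""
        assert parts[1:-1] == [sp.spacer for sp in spacers]

    def test_empty_inputs_rejected(self):
        with pytest.raises(DesignError):
            assemble_array([], "GG")
        with pytest.raises(DesignError):
            assemble_array(["AAAA"], "")


def validate_plan(plan, n):
    """Brute-force validation: leaf sizes, coverage, one-spacer overlaps."""
    covered = set()
    for frag in plan.level0:
        assert 3 <= frag.n_spacers <= 4
        covered.update(range(frag.first, frag.last + 1))
    assert covered == set(range(1, n + 1))
    produced = {(f.first, f.last) for f in plan.level0}
    for join in plan.joins:
        left, right = join.left, join.right
        assert (left.first, left.last) in produced
        assert (right.first, right.last) in produced
        overlap = set(range(left.first, left.last + 1)) & set(
            range(right.first, right.last + 1)
        )
        if join.overhang_spacer is None:
            assert len(overlap) == 1
        else:
            assert len(overlap) == 0
            assert join.overhang_spacer == right.first  # overhang creates it
        assert join.product.first == left.first
        assert join.product.last == right.last
        produced.add((join.product.first, join.product.last))
    assert (1, n) in produced


class TestFragmentPlan:
    def test_24_spacer_plan_matches_published_build(self):
        plan = plan_fragments(24)
        assert [str(f) for f in plan.level0] == [
            "spacers 1-4", "spacers 4-6", "spacers 6-9", "spacers 9-12",
            "spacers 13-16", "spacers 16-18", "spacers 18-21", "spacers 21-24",
        ]
        top = plan.joins[-1]
        assert (str(top.left), str(top.right)) == ("spacers 1-12", "spacers 13-24")
        assert top.overhang_spacer == 13

    def test_6_spacer_plan_single_join(self):
        plan = plan_fragments(6)
        assert [str(f) for f in plan.level0] == ["spacers 1-4", "spacers 4-6"]
        assert len(plan.joins) == 1

    @pytest.mark.parametrize("n", range(3, 49))
    def test_every_size_plans_validly(self, n):
        validate_plan(plan_fragments(n), n)

    def test_too_few_spacers_rejected(self):
        with pytest.raises(DesignError):
            plan_fragments(2)

    def test_plan_serializes_to_ordered_steps(self):
        steps = plan_fragments(24).to_steps()
        kinds = [s["step"] for s in steps]
        assert kinds.count("amplify") == 8
        assert kinds.count("add_overhang") == 1
        assert kinds.count("join") == 7


class TestTranscriptValidation:
    def test_rna_alphabet_accepted_as_dna(self):
        tx = TargetTranscript("tx", "ACGU" * 10, 0, 40)
        assert "U" not in tx.sequence

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(DesignError):
            TargetTranscript("tx", "ACGX", 0, 4)

    def test_utr_outside_sequence_rejected(self):
        with pytest.raises(DesignError):
            TargetTranscript("tx", "ACGT" * 10, 10, 60)
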