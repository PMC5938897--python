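import math

import pytest

from updown.kappa import KappaTable, generate_patterns
from updown.ladder import Assay, build_ladder
from updown.staircase import (
    MAX_VALID_MARKS,
    CellMark,
    ResponseTable,
    ResultStatus,
    Termination,
    TrialSequence,
    UngrammaticalTableError,
    MissingKappaError,
    ValidityVerdict,
    compute_threshold,
    count_marks,
    kappa_pattern,
    table_to_sequence,
    validity_gate,
)

X, O, E = "X", "O", "."


def mouse_table(*rows, source=None):
    """Build a mouse table from up to five 9-character row strings."""
    rows = list(rows) + ["." * 9] * (5 - len(rows))
    return ResponseTable.from_string(Assay.MOUSE, "".join(rows), source)


@pytest.fixture(scope="module")
def ladder():
    return build_ladder(Assay.MOUSE)


@pytest.fixture(scope="module")
def zero_kappa():
    return KappaTable({p: 0.0 for p in generate_patterns()})


class TestTableToSequence:
    def test_hand_traced_alternating_table(self, ladder):
        # opening X at 0.6g then O at 0.4g, followed by four alternating
        # trials, one per row
        t = mouse_table(
            "...OX....",
            "....X....",
            "...O.....",
            "....X....",
            "...O.....",
        )
        seq = table_to_sequence(t, ladder)
        assert [(i, r.char) for i, r in seq.trials] == [
            (5, X), (4, O), (5, X), (4, O), (5, X), (4, O)
        ]
        assert seq.termination is Termination.COMPLETED
        assert seq.first_change_pos == 2
        assert seq.final_index == 4

    def test_insensitive_subject_out_of_range(self, ladder):
        # all-O first row up to the strongest filament, Figure-1B style
        t = mouse_table("....OOOOO")
        seq = table_to_sequence(t, ladder)
        assert seq.termination is Termination.OOR_HIGH
        assert len(seq.trials) == 5
        assert not seq.completed

    def test_hypersensitive_subject_out_of_range(self, ladder):
        t = mouse_table("XXXXX....")
        seq = table_to_sequence(t, ladder)
        assert seq.termination is Termination.OOR_LOW
        assert len(seq.trials) == 5
        assert seq.trials[0][0] == 5  # read outward from the start column

    def test_out_of_range_below_in_descending_phase(self, ladder):
        # change at the weakest filament in row one, then two positive
        # responses walk back down and fall off the ladder in row three
        t = mouse_table(
            "OXXXX....",
            ".X.......",
            "X........",
        )
        seq = table_to_sequence(t, ladder)
        assert seq.termination is Termination.OOR_LOW
        assert len(seq.trials) == 7
        assert seq.final_index == 1

    def test_two_marks_in_lower_row_rejected(self, ladder):
        t = mouse_table(
            "...OX....",
            "....X....",
            "..OO.....",
        )
        with pytest.raises(UngrammaticalTableError, match="multiple marks"):
            table_to_sequence(t, ladder)

    def test_gap_row_rejected(self, ladder):
        t = mouse_table(
            "...OX....",
            "....X....",
            ".........",
            "....X....",
        )
        with pytest.raises(UngrammaticalTableError, match="gap"):
            table_to_sequence(t, ladder)

    def test_wrong_start_column_rejected(self, ladder):
        t = mouse_table(
            "..OX.....",  # anchored at column 3, not the start column 5
            "..X......",
            "...O.....",
            "..X......",
            "...O.....",
        )
        with pytest.raises(UngrammaticalTableError, match="start column"):
            table_to_sequence(t, ladder)

    def test_inconsistent_direction_rejected(self, ladder):
        # row-one change then a lower-row step that contradicts it
        t = mouse_table(
            "...OX....",
            "..X......",  # after O@4 the next must be 0.6g (col 5)
            "...O.....",
            "....X....",
            "...O.....",
        )
        with pytest.raises(UngrammaticalTableError, match="step"):
            table_to_sequence(t, ladder)

    def test_incomplete_sequence_rejected(self, ladder):
        t = mouse_table("...OX....", "....X....")
        with pytest.raises(UngrammaticalTableError, match="incomplete"):
            table_to_sequence(t, ladder)

    def test_single_mark_first_row_rejected(self, ladder):
        with pytest.raises(UngrammaticalTableError):
            table_to_sequence(mouse_table("....X...."), ladder)

    def test_empty_table_rejected(self, ladder):
        with pytest.raises(UngrammaticalTableError, match="empty"):
            table_to_sequence(mouse_table(), ladder)

    def test_lower_rows_before_change_rejected(self, ladder):
        t = mouse_table(
            "...XX....",  # no response change within row one
            "..X......",
        )
        with pytest.raises(UngrammaticalTableError):
            table_to_sequence(t, ladder)

    def test_width_mismatch_rejected(self, ladder):
        t = ResponseTable.from_string(Assay.HUMAN_MDT, "." * 40)
        with pytest.raises(ValueError, match="width"):
            table_to_sequence(t, ladder)


class TestKappaPattern:
    def test_direct_read_off(self, ladder):
        t = mouse_table(
            "...OX....", "....X....", "...O.....", "....X....", "...O....."
        )
        assert kappa_pattern(table_to_sequence(t, ladder)) == "XOXOXO"

    def test_last_six_rule_on_long_opening_run(self, ladder):
        # row one holds five trials (four O's then the change X); the
        # pattern is trials 4..9
        t = mouse_table(
            "....OOOOX",
            ".......X.",
            "......O..",
            ".......X.",
            "......O..",
        )
        seq = table_to_sequence(t, ladder)
        assert len(seq.trials) == 9
        assert kappa_pattern(seq) == seq.responses()[3:]
        assert kappa_pattern(seq) == "OXXOXO"

    def test_complemented_table_gives_complemented_pattern(self, ladder):
        a = mouse_table(
            "...OX....", "....X....", "...O.....", "....X....", "...O....."
        )
        b = mouse_table(
            "....OX...", "....O....", ".....X...", "....O....", ".....X..."
        )
        pa = kappa_pattern(table_to_sequence(a, ladder))
        pb = kappa_pattern(table_to_sequence(b, ladder))
        assert pb == pa.translate(str.maketrans("XO", "OX"))

    def test_requires_completed_sequence(self, ladder):
        seq = table_to_sequence(mouse_table("....OOOOO"), ladder)
        with pytest.raises(ValueError):
            kappa_pattern(seq)


class TestComputeThreshold:
    def test_zero_kappa_identity(self, ladder, zero_kappa):
        t = mouse_table(
            "...OX....", "....X....", "...O.....", "....X....", "...O....."
        )
        seq = table_to_sequence(t, ladder)
        res = compute_threshold(seq, ladder, zero_kappa)
        assert res.threshold_g == pytest.approx(0.4, abs=1e-12)
        assert res.status is ResultStatus.OK

    def test_oor_high_caps_at_max_force(self, ladder, kappa_table):
        seq = table_to_sequence(mouse_table("....OOOOO"), ladder)
        res = compute_threshold(seq, ladder, kappa_table)
        assert res.threshold_g == 4.0
        assert res.status is ResultStatus.OOR_HIGH
        assert res.kappa_used is None

    def test_oor_low_caps_at_min_force(self, ladder, kappa_table):
        seq = table_to_sequence(mouse_table("XXXXX...."), ladder)
        res = compute_threshold(seq, ladder, kappa_table)
        assert res.threshold_g == 0.04
        assert res.status is ResultStatus.OOR_LOW

    def test_bundled_kappa_applied_on_log_scale(self, ladder, kappa_table):
        t = mouse_table(
            "...OX....", "....X....", "...O.....", "....X....", "...O....."
        )
        seq = table_to_sequence(t, ladder)
        res = compute_threshold(seq, ladder, kappa_table)
        k = kappa_table["XOXOXO"]
        assert res.threshold_g == pytest.approx(
            0.4 * 10 ** (k * 0.25), rel=1e-12
        )
        assert res.pattern == "XOXOXO"
        assert res.final_force_g == 0.4

    def test_missing_kappa_is_loud(self, ladder):
        t = mouse_table(
            "...OX....", "....X....", "...O.....", "....X....", "...O....."
        )
        seq = table_to_sequence(t, ladder)
        with pytest.raises(MissingKappaError):
            compute_threshold(seq, ladder, KappaTable({}))


class TestMarkCountGate:
    def test_empty_table_counts_zero(self):
        assert count_marks(mouse_table()) == 0
        assert validity_gate(mouse_table()) is ValidityVerdict.VALID

    def test_figure_style_minimal_table(self):
        assert count_marks(mouse_table("....OOOOO")) == 5

    def test_fully_struck_table(self):
        t = ResponseTable.from_string(Assay.MOUSE, "X" * 45)
        assert count_marks(t) == 45
        assert validity_gate(t) is ValidityVerdict.INVALID_OVERMARKED

    def test_gate_boundary_is_exclusive_at_twelve(self):
        assert MAX_VALID_MARKS == 12
        # the gate counts marks only; grammar is judged downstream
        t12 = ResponseTable.from_string(
            Assay.MOUSE, "X" * 12 + "." * 33
        )
        assert count_marks(t12) == 12
        assert validity_gate(t12) is ValidityVerdict.VALID
        t13 = ResponseTable.from_string(
            Assay.MOUSE, "X" * 13 + "." * 32
        )
        assert count_marks(t13) == 13
        assert validity_gate(t13) is ValidityVerdict.INVALID_OVERMARKED


class TestResponseTable:
    def test_string_round_trip(self):
        text = "...OX...." "....X...." "...O....." "....X...." "...O....."
        t = ResponseTable.from_string(Assay.MOUSE, text)
        assert t.to_string() == text

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ResponseTable.from_string(Assay.MOUSE, "X" * 44)

    def test_bad_character_rejected(self):
        with pytest.raises(ValueError):
            ResponseTable.from_string(Assay.MOUSE, "Z" + "." * 44)

    def test_row_count_enforced(self):
        with pytest.raises(ValueError, match="rows"):
            ResponseTable(
                Assay.MOUSE, tuple([tuple([CellMark.EMPTY] * 9)] * 4)
            )
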