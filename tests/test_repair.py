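import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from updown.ladder import Assay, build_ladder
from updown.repair import (
    DEFAULT_REPAIR_CUTOFF,
    Lexicon,
    edit_distance,
    encode_table,
    decode_table,
    repair_table,
)
from updown.staircase import ResponseTable


def dp_levenshtein(a, b):
    """Textbook DP oracle, kept independent of the implementation."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[m][n]


strings = st.text(alphabet="XO.", max_size=20)


class TestEditDistance:
    def test_identity(self):
        assert edit_distance("XOXO", "XOXO") == 0

    def test_insertions(self):
        assert edit_distance("", "XO") == 2

    def test_single_substitution(self):
        assert edit_distance("XOX", "XOO") == 1

    @given(strings, strings)
    @settings(max_examples=200)
    def test_matches_dp_oracle(self, a, b):
        assert edit_distance(a, b) == dp_levenshtein(a, b)

    @given(strings, strings)
    @settings(max_examples=200)
    def test_symmetry(self, a, b):
        assert edit_distance(a, b) == edit_distance(b, a)

    @given(strings, strings)
    @settings(max_examples=100)
    def test_identity_of_indiscernibles(self, a, b):
        assert (edit_distance(a, b) == 0) == (a == b)

    @given(strings, strings, strings)
    @settings(max_examples=200)
    def test_triangle_inequality(self, a, b, c):
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestEncoding:
    def test_all_empty(self):
        t = ResponseTable.from_string(Assay.MOUSE, "." * 45)
        assert encode_table(t) == "." * 45

    def test_single_mark_position(self):
        text = "." * 4 + "X" + "." * 40
        t = ResponseTable.from_string(Assay.MOUSE, text)
        assert encode_table(t) == text

    def test_round_trip_over_lexicon(self, mouse_lexicon):
        for text in mouse_lexicon:
            assert encode_table(decode_table(Assay.MOUSE, text)) == text


class TestRepair:
    def test_lexicon_member_passes_through(self, mouse_lexicon):
        for text in list(mouse_lexicon)[:25]:
            out = repair_table(text, mouse_lexicon)
            assert out.corrected == text
            assert out.distance == 0
            assert not out.ambiguous
            assert out.accepted

    def test_single_flip_recovery_exhaustive(self, mouse_lexicon):
        """Every unique-nearest-neighbour single X<->O corruption is
        restored exactly."""
        checked = unique = 0
        for text in mouse_lexicon:
            for i, ch in enumerate(text):
                if ch == ".":
                    continue
                flipped = (
                    text[:i] + ("O" if ch == "X" else "X") + text[i + 1 :]
                )
                if flipped in mouse_lexicon:
                    continue
                out = repair_table(flipped, mouse_lexicon)
                checked += 1
                assert out.accepted
                assert out.distance == 1
                if not out.ambiguous:
                    unique += 1
                    assert out.corrected == text
        assert checked > 500
        assert unique / checked > 0.9

    def test_tie_case_is_flagged_and_deterministic(self, mouse_lexicon):
        # brute-force search for an observed string equidistant from
        # two or more entries
        entries = mouse_lexicon.entries
        found = None
        for a in entries:
            for b in entries:
                if a >= b:
                    continue
                diff = [i for i in range(len(a)) if a[i] != b[i]]
                if len(diff) != 2:
                    continue
                i = diff[0]
                mid = a[:i] + b[i] + a[i + 1 :]
                if mid in mouse_lexicon:
                    continue
                out = repair_table(mid, mouse_lexicon)
                if out.ambiguous and out.distance == 1:
                    found = (mid, out)
                    break
            if found:
                break
        assert found is not None, "no tie case found by brute force"
        mid, out = found
        again = repair_table(mid, mouse_lexicon)
        assert again == out  # deterministic winner

    def test_confidence_breaks_ties_toward_trusted_cells(self, mouse_lexicon):
        entries = mouse_lexicon.entries
        for a in entries:
            for b in entries:
                if a >= b:
                    continue
                diff = [i for i in range(len(a)) if a[i] != b[i]]
                if len(diff) != 2:
                    continue
                i, j = diff
                mid = a[:i] + b[i] + a[i + 1 :]
                if mid in mouse_lexicon:
                    continue
                out = repair_table(mid, mouse_lexicon)
                if not (out.ambiguous and out.distance == 1):
                    continue
                # trusting cell i pushes the repair away from `a`
                conf = [0.5] * len(mid)
                conf[i] = 1.0
                conf[j] = 0.1
                trusted = repair_table(mid, mouse_lexicon, confidences=conf)
                assert trusted.corrected != a or trusted.corrected == min(a, b)
                return
        pytest.skip("no tie case available")

    def test_cutoff_rejects_garbage(self, mouse_lexicon):
        garbage = "XO" * 22 + "X"
        out = repair_table(garbage, mouse_lexicon)
        assert not out.accepted
        assert out.distance > DEFAULT_REPAIR_CUTOFF

    def test_rejects_foreign_alphabet(self, mouse_lexicon):
        with pytest.raises(ValueError):
            repair_table("Z" * 45, mouse_lexicon)

    def test_empty_lexicon_is_configuration_error(self):
        with pytest.raises(ValueError):
            Lexicon(Assay.MOUSE, [])


class TestLexiconPersistence:
    def test_save_load_round_trip(self, mouse_lexicon, tmp_path):
        p = tmp_path / "mouse.lexicon"
        mouse_lexicon.save(p)
        loaded = Lexicon.load(p)
        assert loaded.entries == mouse_lexicon.entries
        assert loaded.fingerprint == mouse_lexicon.fingerprint

    def test_fingerprint_mismatch_detected(self, mouse_lexicon, tmp_path):
        p = tmp_path / "mouse.lexicon"
        mouse_lexicon.save(p)
        lines = p.read_text().splitlines()
        lines.pop(3)  # drop an entry; header fingerprint now stale
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="fingerprint"):
            Lexicon.load(p)

    def test_non_lexicon_file_rejected(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("hello\n")
        with pytest.raises(ValueError, match="lexicon"):
            Lexicon.load(p)

    def test_build_matches_enumeration(self, mouse_lexicon, lexicons):
        assert set(mouse_lexicon.entries) == lexicons[Assay.MOUSE]
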