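import numpy as np
import pytest

from shadowfold.structure_io import (FormatError, RnaRecord, encode,
                                     length_filter, parse_dotbracket, read_ct,
                                     read_dotbracket_file, shadow_of,
                                     to_dotbracket, write_ct)


class TestRnaRecord:
    def test_rejects_repeated_index(self):
        with pytest.raises(ValueError, match="more than one pair"):
            RnaRecord("x", "f", "A" * 10, frozenset({(1, 8), (1, 9)}))

    def test_rejects_out_of_range_pair(self):
        with pytest.raises(ValueError, match="out of range"):
            RnaRecord("x", "f", "ACGU", frozenset({(1, 5)}))

    def test_crossing_pairs_are_allowed(self):
        rec = RnaRecord("pk", "f", "A" * 20, frozenset({(1, 10), (5, 15)}))
        assert len(rec.pairs) == 2


class TestCt:
    def test_single_pair(self, tmp_path):
        ct = tmp_path / "h.ct"
        ct.write_text(
            "5 hairpin\n"
            "1 G 0 2 5 1\n2 A 1 3 0 2\n3 A 2 4 0 3\n4 A 3 5 0 4\n5 C 4 6 1 5\n"
        )
        rec = read_ct(ct)
        assert rec.sequence == "GAAAC"
        assert rec.pairs == frozenset({(1, 5)})

    def test_all_unpaired(self, tmp_path):
        ct = tmp_path / "u.ct"
        ct.write_text("3 t\n1 A 0 2 0 1\n2 C 1 3 0 2\n3 G 2 4 0 3\n")
        assert read_ct(ct).pairs == frozenset()

    def test_inconsistent_partner_raises(self, tmp_path):
        ct = tmp_path / "bad.ct"
        ct.write_text("5 t\n1 G 0 2 5 1\n2 A 1 3 0 2\n3 A 2 4 0 3\n"
                      "4 A 3 5 0 4\n5 C 4 6 2 5\n")
        with pytest.raises(FormatError, match="inconsistent"):
            read_ct(ct)

    def test_non_integer_field_raises(self, tmp_path):
        ct = tmp_path / "bad.ct"
        ct.write_text("1 t\n1 A 0 2 x 1\n")
        with pytest.raises(FormatError):
            read_ct(ct)

    def test_write_fills_both_directions(self, tmp_path):
        rec = RnaRecord("s", "f", "GAAAC", frozenset({(1, 5)}))
        path = tmp_path / "s.ct"
        write_ct(rec, path)
        rows = path.read_text().splitlines()[1:]
        assert rows[0].split()[4] == "5"
        assert rows[4].split()[4] == "1"

    def test_roundtrip_on_random_records(self, tmp_path, random_records):
        for rec in random_records[:50]:
            path = tmp_path / "r.ct"
            write_ct(rec, path)
            back = read_ct(path)
            assert back.sequence == rec.sequence
            assert back.pairs == rec.pairs


class TestDotBracket:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("...(((....))).", {(4, 13), (5, 12), (6, 11)}),
            ("....", set()),
            ("((..[[..))..]]", {(1, 10), (2, 9), (5, 14), (6, 13)}),
        ],
    )
    def test_parse(self, s, expected):
        assert parse_dotbracket(s) == frozenset(expected)

    @pytest.mark.parametrize("s", ["(((", "..)", "[..", "(]"])
    def test_unbalanced_raises(self, s):
        with pytest.raises(FormatError):
            parse_dotbracket(s)

    def test_render_nested(self):
        rec = RnaRecord("x", "f", "A" * 14,
                        frozenset({(4, 13), (5, 12), (6, 11)}))
        assert to_dotbracket(rec) == "...(((....)))."

    def test_roundtrip_including_pseudoknots(self, random_records):
        for rec in random_records:
            assert parse_dotbracket(to_dotbracket(rec)) == rec.pairs

    def test_crossing_pairs_use_second_layer(self):
        rec = RnaRecord("pk", "f", "A" * 14,
                        frozenset({(1, 10), (2, 9), (5, 14), (6, 13)}))
        db = to_dotbracket(rec)
        assert "[" in db and "]" in db
        assert parse_dotbracket(db) == rec.pairs


class TestShadowAndEncoding:
    def test_shadow_worked_example(self):
        rec = RnaRecord("x", "f", "A" * 14,
                        frozenset(parse_dotbracket("...(((....))).")))
        assert list(shadow_of(rec)) == [0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 0]

    def test_shadow_sums_to_twice_pairs(self, random_records):
        for rec in random_records[:50]:
            assert shadow_of(rec).sum() == 2 * len(rec.pairs)

    def test_fully_paired_even_record(self):
        rec = RnaRecord("x", "f", "GGGGGCCCCC",
                        frozenset({(i, 11 - i) for i in range(1, 6)}))
        assert shadow_of(rec).tolist() == [1] * 10

    def test_onehot_columns(self):
        rec = RnaRecord("x", "f", "UCG")
        enc = encode(rec, pad_to=8)
        assert enc.x[:, 0].tolist() == [0, 0, 0, 1]  # U
        assert enc.x[:, 1].tolist() == [0, 1, 0, 0]  # C
        assert enc.x[:, 2].tolist() == [0, 0, 1, 0]  # G
        assert enc.x[:, 3:].sum() == 0
        assert enc.true_length == 3

    def test_ambiguity_letter_is_zero_column(self):
        enc = encode(RnaRecord("x", "f", "ANU"), pad_to=4)
        assert enc.x[:, 1].sum() == 0
        assert enc.x[:, 0].sum() == 1 and enc.x[:, 2].sum() == 1

    def test_nonzero_column_count_equals_length(self, random_records):
        for rec in random_records[:20]:
            enc = encode(rec, pad_to=128)
            assert (enc.x.sum(axis=0) > 0).sum() == enc.true_length

    def test_too_long_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            encode(RnaRecord("x", "f", "ACGUA"), pad_to=4)


class TestLengthFilter:
    def test_removes_only_long_records(self):
        rng = np.random.default_rng(0)
        recs = [RnaRecord(f"r{i}", "f", "A" * int(n))
                for i, n in enumerate(rng.integers(50, 600, size=100))]
        kept = length_filter(recs, max_len=512)
        assert all(len(r) <= 512 for r in kept)
        assert [r.id for r in kept] == [r.id for r in recs if len(r) <= 512]

    def test_identity_when_all_short(self, tiny_corpus):
        assert length_filter(tiny_corpus, 512) == list(tiny_corpus)

    def test_empty_input(self):
        assert length_filter([], 512) == []


def test_read_dotbracket_file(tmp_path):
    f = tmp_path / "s.db"
    f.write_text("GGGAAACCC\n(((...)))\n")
    rec = read_dotbracket_file(f)
    assert rec.pairs == frozenset({(1, 9), (2, 8), (3, 7)})
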