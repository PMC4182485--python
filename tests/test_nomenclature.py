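"""Anchoring, isomiR naming and seed-code round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedatlas import (
    AlphabetError,
    CodeUndefinedError,
    Hairpin,
    IsomiRDesignation,
    NoAnchorError,
    OutOfBoundsError,
    ParseError,
    anchor_hairpin,
    derive_seed,
    mature_sequence,
    parse_seed_code,
    seed_code,
)
from seedatlas.nomenclature import BLOCK_3P, BLOCK_5P, designation_table, hamming


def _planted(block5="ACUCAAA", block3="AAAGUGC"):
    return "GG" + block5 + "A" * 14 + "GCGC" + "A" * 14 + block3 + "CGCUU"


class TestAnchorHairpin:
    def test_exact_planted_blocks(self):
        assert anchor_hairpin(_planted()) == (2, 41)

    def test_one_mismatch_in_5p_block(self):
        seq = _planted(block5="ACUGAAA")
        assert anchor_hairpin(seq, max_mismatch=1) == (2, 41)

    def test_no_motif_raises_with_best_distance(self):
        with pytest.raises(NoAnchorError) as exc:
            anchor_hairpin("A" * 60, max_mismatch=1)
        assert exc.value.best_distance is not None

    def test_dna_input_accepted(self):
        assert anchor_hairpin(_planted().replace("U", "T")) == (2, 41)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            anchor_hairpin("ACUCAAA" + "AAAGUGC")

    def test_agrees_with_bruteforce_on_random_sequences(self):
        """Exhaustive scan over all offset pairs on random sequences with
        planted, optionally mutated, blocks."""
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGU"))

        def brute(seq, mm):
            best = None
            for a5 in range(len(seq) - 6):
                d5 = hamming(seq[a5:a5 + 7], BLOCK_5P)
                if d5 > mm:
                    continue
                for a3 in range(a5 + 7, len(seq) - 6):
                    d3 = hamming(seq[a3:a3 + 7], BLOCK_3P)
                    if d3 > mm:
                        continue
                    cand = (d5 + d3, a5, a3)
                    if best is None or cand < best:
                        best = cand
            return None if best is None else (best[1], best[2])

        for _ in range(200):
            n = int(rng.integers(60, 91))
            seq = "".join(rng.choice(bases, size=n))
            a5 = int(rng.integers(0, n - 40))
            a3 = int(rng.integers(a5 + 7, n - 7))
            b5, b3 = list(BLOCK_5P), list(BLOCK_3P)
            for block in (b5, b3):
                for p in rng.choice(7, size=int(rng.integers(0, 3)),
                                    replace=False):
                    block[p] = str(rng.choice(bases))
            seq = (seq[:a5] + "".join(b5) + seq[a5 + 7:a3] + "".join(b3)
                   + seq[a3 + 7:])
            expect = brute(seq, 2)
            if expect is None:
                with pytest.raises(NoAnchorError):
                    anchor_hairpin(seq, 2)
            else:
                assert anchor_hairpin(seq, 2) == expect


class TestMatureAndSeed:
    def test_mature_window_at_3p0(self, toy_hairpin):
        d = IsomiRDesignation("toy", "3p", 0, length=7)
        assert mature_sequence(toy_hairpin, d) == "AAAGUGC"

    def test_mature_window_shifted(self, toy_hairpin):
        d = IsomiRDesignation("toy", "3p", 1, length=7)
        assert mature_sequence(toy_hairpin, d) == "AAGUGCC"

    def test_out_of_bounds_negative_shift(self):
        seq = "ACUCAAA" + "A" * 20 + "AAAGUGC" + "A" * 20
        h = Hairpin(id="h", sequence=seq, anchor_5p0=0, anchor_3p0=27)
        with pytest.raises(OutOfBoundsError):
            mature_sequence(h, IsomiRDesignation("h", "5p", -1, length=7))

    @pytest.mark.parametrize("shift,definition,expected", [
        (0, "mer7", "AAGUGCC"),   # (3p)2-7C
        (1, "mer7", "AGUGCCG"),   # (3p)3-7CG
        (2, "mer7", "GUGCCGC"),   # (3p)4-7CGC
        (0, "mer6", "AAGUGC"),    # invariant 3p0 6mer
    ])
    def test_seeds_on_conserved_3p_context(self, shift, definition, expected):
        seq = "GG" + "ACUCAAA" + "A" * 20 + "AAAGUGCCGCC" + "A" * 10
        h = Hairpin(id="h", sequence=seq, anchor_5p0=2, anchor_3p0=29)
        d = IsomiRDesignation("h", "3p", shift)
        assert derive_seed(h, d, definition).sequence == expected

    def test_5p0_mer7_seed(self, mouse):
        hp = {h.id: h for h in mouse.hairpins}
        d = IsomiRDesignation("miR-290", "5p", 0)
        assert derive_seed(hp["miR-290"], d, "mer7").sequence == "CUCAAAC"

    def test_mer6_is_prefix_of_mer7(self, mouse):
        for h in mouse.hairpins:
            for arm in ("5p", "3p"):
                for shift in (-1, 0, 1, 2):
                    d = IsomiRDesignation(h.id, arm, shift)
                    s6 = derive_seed(h, d, "mer6").sequence
                    s7 = derive_seed(h, d, "mer7").sequence
                    assert s7.startswith(s6)

    def test_anchored_mer6_seeds_are_invariant(self, mouse, human):
        for h in mouse.hairpins + human.hairpins:
            d3 = IsomiRDesignation(h.id, "3p", 0)
            d5 = IsomiRDesignation(h.id, "5p", 0)
            assert derive_seed(h, d3, "mer6").sequence == "AAGUGC"
            assert derive_seed(h, d5, "mer6").sequence == "CUCAAA"


class TestSeedCode:
    @pytest.mark.parametrize("arm,shift,definition,expected", [
        ("3p", 1, "mer7", "(3p)3-7CG"),
        ("3p", 2, "mer7", "(3p)4-7CGC"),
        ("3p", 0, "mer7", "(3p)2-7C"),
        ("5p", 0, "mer6", "(5p)2-7"),
    ])
    def test_published_codes(self, mouse, arm, shift, definition, expected):
        hp = {h.id: h for h in mouse.hairpins}
        h = hp["miR-292"]
        assert seed_code(h, IsomiRDesignation(h.id, arm, shift),
                         definition) == expected

    def test_code_undefined_when_window_off_block(self, mouse):
        h = mouse.hairpins[0]
        with pytest.raises(CodeUndefinedError):
            seed_code(h, IsomiRDesignation(h.id, "3p", 7), "mer7")

    @pytest.mark.parametrize("code,expected", [
        ("(3p)4-7CGC", ("3p", 2, "CGC", "mer7")),
        ("(5p)2-7", ("5p", 0, "", "mer6")),
        ("(3p)2-7U", ("3p", 0, "U", "mer7")),
    ])
    def test_parse_examples(self, code, expected):
        p = parse_seed_code(code)
        assert (p.arm, p.shift, p.bases, p.definition) == expected

    @pytest.mark.parametrize("bad", ["(3p)9-7", "3p2-7", "(3p)27", "(2p)2-7"])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(ParseError):
            parse_seed_code(bad)

    def test_round_trip_all_shifts(self, mouse, human):
        """parse(format(d)) reproduces arm/shift/definition for |shift|<=3."""
        for h in mouse.hairpins + human.hairpins:
            for arm in ("5p", "3p"):
                for shift in range(-3, 4):
                    for definition in ("mer6", "mer7"):
                        d = IsomiRDesignation(h.id, arm, shift)
                        code = seed_code(h, d, definition)
                        p = parse_seed_code(code)
                        assert (p.arm, p.shift, p.definition) == \
                            (arm, shift, definition)


class TestSeedCodeProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        ext5=st.text(alphabet="ACGU", min_size=12, max_size=12),
        ext3=st.text(alphabet="ACGU", min_size=12, max_size=12),
        arm=st.sampled_from(["5p", "3p"]),
        shift=st.integers(min_value=-3, max_value=3),
        definition=st.sampled_from(["mer6", "mer7"]),
    )
    def test_round_trip_and_prefix_on_random_contexts(self, ext5, ext3, arm,
                                                      shift, definition):
        """On arbitrary flanking contexts: codes round-trip, and the mer6
        seed is always the mer7 seed's 6-nt prefix."""
        seq = "GGGG" + "ACUCAAA" + ext5 + "AAAGUGC" + ext3
        h = Hairpin(id="h", sequence=seq, anchor_5p0=4, anchor_3p0=23)
        d = IsomiRDesignation("h", arm, shift)
        p = parse_seed_code(seed_code(h, d, definition))
        assert (p.arm, p.shift, p.definition) == (arm, shift, definition)
        s6 = derive_seed(h, d, "mer6")
        s7 = derive_seed(h, d, "mer7")
        assert s7.sequence.startswith(s6.sequence)


class TestNamesAndTables:
    @pytest.mark.parametrize("name,fields", [
        ("miR-292-3p+1", ("miR-292", "3p", 1)),
        ("miR-290-5p0", ("miR-290", "5p", 0)),
        ("hp01-3p-2", ("hp01", "3p", -2)),
    ])
    def test_name_round_trip(self, name, fields):
        d = IsomiRDesignation.parse(name)
        assert (d.hairpin_id, d.arm, d.shift) == fields
        assert d.name == name

    def test_alphabet_errors_propagate(self):
        with pytest.raises(AlphabetError):
            Hairpin(id="h", sequence="ACGN" * 15, anchor_5p0=2, anchor_3p0=30)

    def test_designation_table_columns(self, mouse):
        df = designation_table(mouse.hairpins, shifts=(0, 1))
        assert list(df.columns) == ["hairpin_id", "arm", "shift", "length",
                                    "seed6", "seed7", "code6", "code7"]
        row = df[(df.hairpin_id == "miR-292") & (df.arm == "3p")
                 & (df["shift"] == 1)].iloc[0]
        assert row.seed7 == "AGUGCCG" and row.code7 == "(3p)3-7CG"
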