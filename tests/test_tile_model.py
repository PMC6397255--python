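"""Tile grammar, printed-segment complementarities and the activation cascade."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhtpoly import (
    HelixGeometry,
    ReactionSystem,
    crossover_turns_and_side,
    reverse_complement,
    sdr_cascade,
    symmetry_score,
    tile_dimensions,
    validate_system,
    validate_tile,
)
from dhtpoly.tile_model import StrandSpec

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TGAACC", "GGTTCA"),  # A's loop invades B's toehold
            ("GTGACA", "TGTCAC"),  # B's exposed segment invades A's toehold
            ("", ""),
            ("ACGT", "ACGT"),
        ],
    )
    def test_known_pairs(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestValidateTile:
    def test_generator_tiles_are_clean(self, tile_system):
        assert validate_system(tile_system) == []

    def test_sticky_end_mutation_is_one_violation(self, tile_system):
        tiles = dict(tile_system.tiles)
        b = tiles["B"]
        b2 = b.strand("b2")
        seq = list(b2.sequence)
        seq[0] = "A" if seq[0] != "A" else "C"  # inside the 5' sticky end
        strands = [
            StrandSpec(b2.name, "".join(seq), b2.labels) if s.name == "b2" else s
            for s in b.strands
        ]
        tiles["B"] = dataclasses.replace(b, strands=strands)
        broken = ReactionSystem(tiles=tiles, initiator=tile_system.initiator)
        violations = [v for v in validate_system(broken)
                      if v.rule == "sticky_pair_mismatch"]
        # the a2~b2 pair is declared on both tiles, so the same mismatch is
        # reported from each side; each report names the same broken pair
        assert len(violations) == 2
        assert all("b2" in v.location or v.tile_id == "B" for v in violations)

    def test_stem_mutation_flags_stem_mismatch(self, tile_system):
        tiles = dict(tile_system.tiles)
        a = tiles["A"]
        stem = a.domains_on("a4", "stem")[0]
        a4 = a.strand("a4")
        seq = list(a4.sequence)
        seq[stem.start] = "A" if seq[stem.start] != "A" else "C"
        strands = [
            StrandSpec(a4.name, "".join(seq), a4.labels) if s.name == "a4" else s
            for s in a.strands
        ]
        tiles["A"] = dataclasses.replace(a, strands=strands)
        broken = ReactionSystem(tiles=tiles, initiator=tile_system.initiator)
        rules = {v.rule for v in validate_tile(broken.tiles["A"], broken)}
        assert "stem_mismatch" in rules

    def test_wrong_strand_count(self, tile_system):
        a = tile_system.tiles["A"]
        crippled = dataclasses.replace(a, strands=a.strands[:3])
        rules = {v.rule for v in validate_tile(crippled)}
        assert "strand_count" in rules


class TestSdrCascade:
    def test_closed_three_event_cycle(self, tile_system):
        events = sdr_cascade(tile_system)
        assert [e.target for e in events] == ["A", "B", "A"]
        assert events[-1].closes_cycle
        # the closing segment is sequence-identical to the initiator's
        # 3' active segment — the regeneration that makes growth living
        assert events[-1].segment == tile_system.initiator_active_segment()

    def test_no_initiator_no_events(self, tile_system):
        silent = ReactionSystem(tiles=tile_system.tiles, initiator=None)
        assert sdr_cascade(silent) == []

    def test_scrambled_b_toehold_halts_after_one_event(self, tile_system):
        tiles = dict(tile_system.tiles)
        b = tiles["B"]
        toe = b.domains_with_role("toehold")[0]
        b3 = b.strand(toe.strand)
        seq = list(b3.sequence)
        seq[toe.start : toe.end] = list("AAAAAA")
        strands = [
            StrandSpec(b3.name, "".join(seq), b3.labels) if s.name == b3.name else s
            for s in b.strands
        ]
        tiles["B"] = dataclasses.replace(b, strands=strands)
        events = sdr_cascade(ReactionSystem(tiles=tiles,
                                            initiator=tile_system.initiator))
        assert [e.target for e in events] == ["A"]

    def test_empty_system_is_an_error(self):
        with pytest.raises(ValueError):
            sdr_cascade(ReactionSystem(tiles={}))

    def test_activation_edges_derivable_from_sequence(self, tile_system):
        edges = set(tile_system.activation_edges())
        assert {("I", "A"), ("A", "B"), ("B", "A")} <= edges


class TestCrossoverGeometry:
    @pytest.mark.parametrize(
        "sep,turns,side",
        [(26, 26 / 10.5, "same"), (32, 32 / 10.5, "opposite"), (21, 2.0, "opposite")],
    )
    def test_printed_separations(self, sep, turns, side):
        t, s = crossover_turns_and_side(sep)
        assert t == pytest.approx(turns)
        assert s == side

    def test_scale_consistency(self):
        # doubling separation and bp/turn together leaves (turns, side) fixed
        for sep in (21, 26, 32, 37):
            base = crossover_turns_and_side(sep)
            doubled = crossover_turns_and_side(
                2 * sep, HelixGeometry(bp_per_turn=21.0)
            )
            assert doubled[0] == pytest.approx(base[0])
            assert doubled[1] == base[1]

    def test_nonpositive_separation(self):
        with pytest.raises(ValueError):
            crossover_turns_and_side(0)


class TestTileDimensions:
    def test_tile_and_duplex_lengths(self, tile_system):
        a = tile_system.tiles["A"]
        thickness, width, length = tile_dimensions(a)
        assert length == pytest.approx(47 * 0.34)     # ~16 nm tile
        assert width == pytest.approx(5.0)            # 2 x 2.25 + 0.5 gap
        assert thickness == pytest.approx(2.25)
        b = dataclasses.replace(a, tile_length_bp=24)
        assert tile_dimensions(b)[2] == pytest.approx(8.16)  # 24-bp duplex

    def test_zero_length_is_error(self, tile_system):
        bad = dataclasses.replace(tile_system.tiles["A"], tile_length_bp=0)
        with pytest.raises(ValueError):
            tile_dimensions(bad)


class TestSymmetryScore:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [("ACGTACGT", 4, 1), ("ACGT", 4, 0), ("AACCGGTT", 1, 4)],
    )
    def test_examples(self, seq, k, expected):
        assert symmetry_score(seq, k) == expected

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            symmetry_score("ACGT", 5)

    @given(dna.filter(lambda s: len(s) >= 6))
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force(self, seq):
        k = 3
        kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        expected = sum(1 for km in set(kmers) if kmers.count(km) > 1)
        assert symmetry_score(seq, k) == expected
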