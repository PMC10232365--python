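"""Fusion-state encoding, quartet classification, and matrix assembly."""

import itertools

import pytest

from synphy.characters import (build_character_matrix, classify_quartet,
                               encode_fusion_state)
from synphy.errors import InputError
from tests.conftest import make_genome


class TestEncodeFusionState:
    def test_separate_chromosomes_give_state_zero(self):
        g = make_genome("T", {"chr1": ["x1", "x2", "x3"],
                              "chr2": ["y1", "y2", "y3"]})
        state, _ = encode_fusion_state(g, {"x1", "x2", "x3"}, {"y1", "y2", "y3"})
        assert state == "0"

    def test_segregated_coresidence_gives_fused_unmixed(self):
        g = make_genome("T", {"chr1": [f"x{i}" for i in range(5)]
                              + [f"y{i}" for i in range(5)]})
        state, res = encode_fusion_state(g, {f"x{i}" for i in range(5)},
                                         {f"y{i}" for i in range(5)})
        assert state == "1"
        assert res.alpha < 0.05

    def test_alternating_coresidence_gives_fused_mixed(self):
        genes = []
        for i in range(5):
            genes += [f"x{i}", f"y{i}"]
        g = make_genome("T", {"chr1": genes})
        state, _ = encode_fusion_state(g, {f"x{i}" for i in range(5)},
                                       {f"y{i}" for i in range(5)})
        assert state == "2"

    def test_split_subgroup_is_unknown_at_default_localization(self):
        g = make_genome("T", {"chr1": ["x1", "x2"], "chr2": ["x3", "x4"],
                              "chr3": ["y1", "y2", "y3", "y4"]})
        state, _ = encode_fusion_state(g, {"x1", "x2", "x3", "x4"},
                                       {"y1", "y2", "y3", "y4"},
                                       localization_fraction=0.8)
        assert state == "?"

    def test_empty_subgroup_is_unknown_not_error(self):
        g = make_genome("T", {"chr1": ["x1"]})
        state, _ = encode_fusion_state(g, {"x1"}, set())
        assert state == "?"

    def test_invariant_to_coordinate_rescaling(self):
        order = ["x0", "y0", "x1", "x2", "y1", "y2"]
        g1 = make_genome("T", {"chr1": order})
        from synphy.genome import GeneLocus, Genome

        rescaled = Genome.from_loci("T", [
            GeneLocus(g, "chr1", (i + 1) * 7919, (i + 1) * 7919 + 3, "+")
            for i, g in enumerate(order)
        ])
        sx, sy = {"x0", "x1", "x2"}, {"y0", "y1", "y2"}
        assert encode_fusion_state(g1, sx, sy)[0] == \
            encode_fusion_state(rescaled, sx, sy)[0]


def oracle_quartet(o, a, b, c):
    """Hand-coded truth table, written independently of the implementation.

    Mapping from (outgroup, A, B, C) fusion states to the quartet pattern:
    missing data anywhere is uninformative; with the outgroup unfused the
    number of fused ingroups decides the pattern (0 none, 1 autapomorphy,
    2 shared synapomorphy - mixing in both = irreversible variant, 3 stem
    fusion = uninformative); with the outgroup fused, an all-unfused ingroup
    is an outgroup-specific change, an all-fused quartet with equal states is
    fully ancestral, mixed ingroup patterns conflict.
    """
    states = (o, a, b, c)
    if "?" in states:
        return "uninformative"
    fused = [s in "12" for s in (a, b, c)]
    n = sum(fused)
    if o == "0":
        if n == 0:
            return "ancestral"
        if n == 1:
            return "single_lineage_fusion"
        if n == 2:
            pair = [s for s, f in zip((a, b, c), fused) if f]
            return ("shared_fusion_with_mixing" if pair == ["2", "2"]
                    else "shared_fusion")
        return "uninformative"
    # outgroup fused
    if n == 0:
        return "outgroup_fusion_or_fission"
    if n == 3:
        return "ancestral"
    return "conflicting"


class TestClassifyQuartet:
    @pytest.mark.parametrize(
        "states,pattern,clade",
        [
            (("0", "0", "2", "2"), "shared_fusion_with_mixing", {"B", "C"}),
            (("0", "0", "1", "1"), "shared_fusion", {"B", "C"}),
            (("0", "0", "0", "2"), "single_lineage_fusion", None),
            (("1", "0", "0", "0"), "outgroup_fusion_or_fission", None),
            (("0", "2", "0", "2"), "shared_fusion_with_mixing", {"A", "C"}),
            (("0", "0", "1", "2"), "shared_fusion", {"B", "C"}),
            (("0", "?", "2", "2"), "uninformative", None),
        ],
    )
    def test_reference_patterns(self, states, pattern, clade):
        got_pattern, got_clade = classify_quartet(*states)
        assert got_pattern == pattern
        assert got_clade == (frozenset(clade) if clade else None)

    def test_full_truth_table_against_oracle(self):
        for states in itertools.product("012?", repeat=4):
            got, clade = classify_quartet(*states)
            assert got == oracle_quartet(*states), states
            if got == "shared_fusion_with_mixing":
                # exactly the two state-2 ingroups are implied as a clade
                expected = {
                    name for name, s in zip("ABC", states[1:]) if s == "2"
                }
                assert clade == frozenset(expected)

    def test_invalid_state_is_input_error(self):
        with pytest.raises(InputError):
            classify_quartet("0", "0", "3", "2")


class TestBuildCharacterMatrix:
    def genomes(self):
        fused = []
        for i in range(5):
            fused += [f"x{i}", f"y{i}"]
        return {
            "T1": make_genome("T1", {"chr1": [f"x{i}" for i in range(5)],
                                     "chr2": [f"y{i}" for i in range(5)]}),
            "T2": make_genome("T2", {"chr1": fused}),
        }

    def test_states_per_taxon(self):
        pairs = [("gx", "gy",
                  {"T1": {f"x{i}" for i in range(5)}, "T2": {f"x{i}" for i in range(5)}},
                  {"T1": {f"y{i}" for i in range(5)}, "T2": {f"y{i}" for i in range(5)}})]
        m = build_character_matrix(self.genomes(), pairs)
        assert m.row("T1") == "0"
        assert m.row("T2") == "2"

    def test_taxon_without_members_scores_unknown(self):
        pairs = [("gx", "gy",
                  {"T1": {f"x{i}" for i in range(5)}},
                  {"T1": {f"y{i}" for i in range(5)}})]
        m = build_character_matrix(self.genomes(), pairs)
        assert m.row("T2") == "?"

    def test_duplicate_pair_label_is_input_error(self):
        pair = ("gx", "gy", {"T1": {"x1"}}, {"T1": {"y1"}})
        with pytest.raises(InputError):
            build_character_matrix(self.genomes(), [pair, pair])

    def test_empty_pair_list_gives_empty_matrix(self):
        assert len(build_character_matrix(self.genomes(), [])) == 0


def test_nexus_export_contains_matrix_and_step_matrix(tmp_path, reported_matrix):
    from synphy.phylo import DEFAULT_STEPS

    out = tmp_path / "m.nex"
    reported_matrix.write_nexus(out, DEFAULT_STEPS.cost, mrbayes_block=True)
    text = out.read_text()
    assert "DIMENSIONS NTAX=5 NCHAR=7" in text
    assert 'SYMBOLS="012"' in text
    assert "USERTYPE" in text and "STEPMATRIX" in text
    assert "MRBAYES" in text
    assert "0022211" in text.replace(" ", "") or "SPO" in text
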