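"""Reciprocal best hits, n-way cliques, and anchor-based joining."""

import itertools

import numpy as np
import pytest

from synphy.errors import InputError
from synphy.genome import SimilarityHits
from synphy.orthology import (OrthoGroup, PairOrthologyMap,
                              merge_groups_by_anchor, nway_groups,
                              read_orthogroup_tsv, reciprocal_best_hits)


def hits(*rows) -> SimilarityHits:
    h = SimilarityHits()
    for q, t, b in rows:
        h.add(q, t, b, 1e-10)
    return h


class TestReciprocalBestHits:
    def test_single_symmetric_pair(self):
        pairs = reciprocal_best_hits(hits(("a1", "b1", 100)), hits(("b1", "a1", 100)))
        assert pairs.pairs == {("a1", "b1")}

    def test_only_mutual_maxima_pair_up(self):
        ab = hits(("a1", "b1", 100), ("a1", "b2", 90), ("a2", "b2", 80))
        ba = hits(("b1", "a1", 100), ("b2", "a2", 80))
        # brute-force oracle: best target per query in each direction
        best_ab = {"a1": "b1", "a2": "b2"}
        best_ba = {"b1": "a1", "b2": "a2"}
        expected = {(a, b) for a, b in best_ab.items() if best_ba[b] == a}
        assert reciprocal_best_hits(ab, ba).pairs == expected == {
            ("a1", "b1"), ("a2", "b2")
        }

    def test_tied_best_score_drops_the_query(self):
        ab = hits(("a1", "b1", 100), ("a1", "b2", 100))
        ba = hits(("b1", "a1", 100), ("b2", "a1", 90))
        assert reciprocal_best_hits(ab, ba).pairs == set()

    def test_shared_query_namespace_is_input_error(self):
        with pytest.raises(InputError):
            reciprocal_best_hits(hits(("a1", "b1", 10)), hits(("a1", "b1", 10)))

    def test_rbh_is_symmetric_under_direction_swap(self):
        rng = np.random.default_rng(42)
        a_genes = [f"a{i}" for i in range(20)]
        b_genes = [f"b{i}" for i in range(20)]
        ab, ba = SimilarityHits(), SimilarityHits()
        for q in a_genes:
            for t in rng.choice(b_genes, size=5, replace=False):
                ab.add(q, str(t), float(rng.integers(10, 200)), 1e-5)
        for q in b_genes:
            for t in rng.choice(a_genes, size=5, replace=False):
                ba.add(q, str(t), float(rng.integers(10, 200)), 1e-5)
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert fwd.pairs == {(a, b) for b, a in rev.pairs}


def pair_map(*pairs) -> PairOrthologyMap:
    return PairOrthologyMap(pairs)


class TestNwayGroups:
    def test_full_triangle_forms_one_group(self):
        maps = {
            ("A", "B"): pair_map(("a1", "b1")),
            ("B", "C"): pair_map(("b1", "c1")),
            ("A", "C"): pair_map(("a1", "c1")),
        }
        groups = nway_groups(maps, ["A", "B", "C"])
        assert {g.members["A"] for g in groups} == {"a1"}

    def test_broken_clique_excludes_the_tuple(self):
        maps = {
            ("A", "B"): pair_map(("a1", "b1")),
            ("B", "C"): pair_map(("b1", "c1")),
            ("A", "C"): pair_map(("a1", "c2")),
        }
        # exhaustive oracle over all (a, b, c) triples
        expected = set()
        for a, b, c in itertools.product(["a1"], ["b1"], ["c1", "c2"]):
            if (("a1", b) in maps[("A", "B")].pairs
                    and (b, c) in maps[("B", "C")].pairs
                    and ("a1", c) in maps[("A", "C")].pairs):
                expected.add((a, b, c))
        assert expected == set()
        assert nway_groups(maps, ["A", "B", "C"]) == set()

    def test_empty_pair_map_gives_empty_output(self):
        maps = {
            ("A", "B"): pair_map(),
            ("B", "C"): pair_map(("b1", "c1")),
            ("A", "C"): pair_map(("a1", "c1")),
        }
        assert nway_groups(maps, ["A", "B", "C"]) == set()

    def test_missing_pair_map_names_the_pair(self):
        with pytest.raises(InputError, match=r"missing pair map.*C"):
            nway_groups({("A", "B"): pair_map(("a1", "b1"))}, ["A", "B", "C"])

    def test_invariant_to_species_ordering(self):
        maps = {
            ("A", "B"): pair_map(("a1", "b1"), ("a2", "b2")),
            ("B", "C"): pair_map(("b1", "c1"), ("b2", "c2")),
            ("A", "C"): pair_map(("a1", "c1")),
        }
        results = [
            nway_groups(maps, order)
            for order in itertools.permutations(["A", "B", "C"])
        ]
        assert all(r == results[0] for r in results)
        # group count bounded by the smallest pair map
        assert len(results[0]) <= min(len(m) for m in maps.values())


def og(**members) -> OrthoGroup:
    return OrthoGroup.from_members(members)


class TestMergeByAnchor:
    ANCHORS = ["HCA", "EMU", "RES"]

    def test_identical_anchor_tuples_merge(self):
        run1 = {og(COW="x1", HCA="h1", EMU="e1", RES="r1")}
        run2 = {og(SRO="s1", HCA="h1", EMU="e1", RES="r1")}
        merged = merge_groups_by_anchor([run1, run2], self.ANCHORS)
        assert len(merged) == 1
        m = next(iter(merged)).members
        assert m == {"COW": "x1", "SRO": "s1", "HCA": "h1", "EMU": "e1", "RES": "r1"}

    def test_differing_anchor_gene_prevents_merge(self):
        run1 = {og(COW="x1", HCA="h1", EMU="e1", RES="r1")}
        run2 = {og(SRO="s1", HCA="h1", EMU="e2", RES="r1")}
        merged = merge_groups_by_anchor([run1, run2], self.ANCHORS)
        assert len(merged) == 2

    def test_single_run_passes_through(self):
        run = {og(COW="x1", HCA="h1", EMU="e1", RES="r1")}
        merged = merge_groups_by_anchor([run], self.ANCHORS)
        assert [g.members for g in merged] == [
            {"COW": "x1", "HCA": "h1", "EMU": "e1", "RES": "r1"}
        ]

    def test_group_missing_anchor_is_input_error(self):
        with pytest.raises(InputError):
            merge_groups_by_anchor([{og(COW="x1", HCA="h1", EMU="e1")}], self.ANCHORS)

    def test_conflicting_non_anchor_gene_sets_flag(self):
        run1 = {og(COW="x1", HCA="h1", EMU="e1", RES="r1")}
        run2 = {og(COW="x2", SRO="s1", HCA="h1", EMU="e1", RES="r1")}
        merged = merge_groups_by_anchor([run1, run2], self.ANCHORS)
        assert len(merged) == 1
        assert next(iter(merged)).conflict_flag


class TestOrthogroupTsv:
    def test_single_copy_rows_become_groups(self, tmp_path):
        p = tmp_path / "og.tsv"
        p.write_text(
            "A\tB\tC\n"
            "a1\tb1\tc1\n"          # kept
            "a2,a3\tb2\tc2\n"      # multi-copy, dropped
            "a4\t\tc4\n"            # empty cell, dropped
        )
        groups = read_orthogroup_tsv(p, ["A", "B", "C"])
        assert {g.members["A"] for g in groups} == {"a1"}

    def test_unknown_species_column_is_input_error(self, tmp_path):
        p = tmp_path / "og.tsv"
        p.write_text("A\tB\na1\tb1\n")
        with pytest.raises(InputError):
            read_orthogroup_tsv(p, ["A", "Z"])
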