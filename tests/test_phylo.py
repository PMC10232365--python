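"""Sankoff parsimony, topology enumeration, likelihood, and MCMC behavior."""

import itertools

import numpy as np
import pytest

from synphy.characters import CharacterMatrix, FusionCharacter
from synphy.errors import InputError
from synphy.phylo import (DEFAULT_STEPS, Node, RateModel, StepMatrix,
                          enumerate_topologies, log_likelihood,
                          mcmc_posterior, parsimony_search, sankoff_cost,
                          transition_matrices, tree_from_newick)

INF = float("inf")


def matrix_from_rows(rows: dict[str, str]) -> CharacterMatrix:
    taxa = list(rows)
    n = len(next(iter(rows.values())))
    chars = [
        FusionCharacter((f"c{j}", "p"), tuple((t, rows[t][j]) for t in taxa))
        for j in range(n)
    ]
    return CharacterMatrix(taxa, chars)


class TestEnumerateTopologies:
    @pytest.mark.parametrize("n_ingroup,expected", [(2, 1), (3, 3), (4, 15)])
    def test_known_topology_counts(self, n_ingroup, expected):
        taxa = ["OUT"] + [f"T{i}" for i in range(n_ingroup)]
        trees = enumerate_topologies(taxa, "OUT")
        assert len(trees) == expected
        # each exactly once
        assert len({t.newick(lengths=False) for t in trees}) == expected
        # outgroup pinned at the root
        for t in trees:
            assert any(c.name == "OUT" for c in t.children)

    def test_too_many_taxa_directs_to_mcmc(self):
        with pytest.raises(InputError, match="MCMC"):
            enumerate_topologies([f"T{i}" for i in range(11)], "T0")


def brute_force_parsimony(matrix: CharacterMatrix, tree: Node,
                          steps: StepMatrix) -> float:
    """Independent oracle: minimize total edge cost over every assignment of
    states to internal nodes."""
    cost = steps.as_array()
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    parents = {id(n): p for p in nodes for n in p.children}
    total = 0.0
    for j in range(len(matrix)):
        best = INF
        leaf_state = {t: matrix.state(t, j) for t in matrix.taxa}
        for assign in itertools.product(range(3), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            c = 0.0
            for n in nodes:
                if n is tree:
                    continue
                ps = amap[id(parents[id(n)])]
                if n.is_leaf:
                    s = leaf_state[n.name]
                    c += 0.0 if s == "?" else cost[ps][int(s)]
                else:
                    c += cost[ps][amap[id(n)]]
                if c >= best:
                    break
            best = min(best, c)
        total += best
    return total


CTENO_SISTER = "(OUT,(CTE,(SPO,(CNI,BIL))));"
SPONGE_SISTER = "(OUT,(SPO,(CTE,(CNI,BIL))));"


class TestSankoffCost:
    def character(self):
        return matrix_from_rows(
            {"OUT": "0", "CTE": "0", "SPO": "2", "CNI": "2", "BIL": "2"}
        )

    def test_shared_mixing_costs_two_on_ctenophore_sister(self):
        total, per = sankoff_cost(self.character(), tree_from_newick(CTENO_SISTER))
        assert total == 2.0
        oracle = brute_force_parsimony(self.character(),
                                       tree_from_newick(CTENO_SISTER), DEFAULT_STEPS)
        assert total == oracle

    def test_same_character_costs_four_on_sponge_sister(self):
        total, _ = sankoff_cost(self.character(), tree_from_newick(SPONGE_SISTER))
        assert total == 4.0
        oracle = brute_force_parsimony(self.character(),
                                       tree_from_newick(SPONGE_SISTER), DEFAULT_STEPS)
        assert total == oracle

    def test_constant_character_costs_nothing(self):
        m = matrix_from_rows({t: "1" for t in ["A", "B", "C", "D"]})
        tree = enumerate_topologies(["A", "B", "C", "D"], "A")[0]
        assert sankoff_cost(m, tree)[0] == 0.0

    def test_taxon_mismatch_is_input_error(self):
        m = matrix_from_rows({"A": "0", "B": "1"})
        with pytest.raises(InputError):
            sankoff_cost(m, tree_from_newick(CTENO_SISTER))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            n_taxa = int(rng.integers(4, 7))
            taxa = [f"T{i}" for i in range(n_taxa)]
            trees = enumerate_topologies(taxa, "T0")
            tree = trees[rng.integers(len(trees))]
            n_chars = int(rng.integers(1, 11))
            rows = {
                t: "".join(rng.choice(list("012?"), size=n_chars)) for t in taxa
            }
            m = matrix_from_rows(rows)
            got, _ = sankoff_cost(m, tree)
            assert got == brute_force_parsimony(m, tree, DEFAULT_STEPS)


def test_ctenophore_sister_is_unique_parsimony_optimum(reported_matrix):
    """On the reported 7-character matrix the topology placing the
    ctenophore as sister to all other animals is strictly the best of all
    15 rooted ingroup arrangements."""
    ranking = parsimony_search(reported_matrix, "OUT")
    assert len(ranking) == 15
    best_tree, best_cost = ranking[0]
    assert best_tree.newick(lengths=False) == "((((BIL,CNI),SPO),CTE),OUT);"
    assert best_cost < ranking[1][1]


class TestIrreversibility:
    def test_no_probability_flows_out_of_the_mixed_state(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            model = RateModel(*rng.exponential(1.0, 3), unmixing=0.0)
            p = transition_matrices(model, rng.exponential(0.5, 4))
            assert np.allclose(p[:, 2, :], [0.0, 0.0, 1.0])
            assert np.allclose(p.sum(axis=2), 1.0, atol=1e-12)

    def test_closed_form_matches_generic_expm(self):
        from scipy.linalg import expm

        rng = np.random.default_rng(4)
        for _ in range(10):
            model = RateModel(*rng.exponential(1.0, 3), unmixing=0.0)
            lengths = rng.exponential(0.5, 3)
            p = transition_matrices(model, lengths)
            for t, pt in zip(lengths, p):
                assert np.allclose(pt, expm(model.q_matrix() * t), atol=1e-9)

    def test_state_two_ancestor_with_state_zero_leaf_has_zero_likelihood(self):
        m = matrix_from_rows({"A": "0", "B": "2", "C": "2", "D": "2"})
        for tree in enumerate_topologies(["A", "B", "C", "D"], "A"):
            for n in tree.postorder():
                n.length = 0.5
            # rooting the process in the mixed state makes the unfused leaf
            # impossible under irreversibility
            assert log_likelihood(m, tree, RateModel(), root_state=2) == -INF
            # but the same data are possible from the separate root state
            assert np.isfinite(log_likelihood(m, tree, RateModel(), root_state=0))


class TestMcmc:
    def test_requires_minimum_generations_and_data(self, reported_matrix):
        with pytest.raises(InputError):
            mcmc_posterior(reported_matrix, generations=10)
        with pytest.raises(InputError):
            mcmc_posterior(CharacterMatrix(["A", "B"], []), generations=2000)

    def test_bad_constraint_is_input_error(self, reported_matrix):
        with pytest.raises(InputError):
            mcmc_posterior(reported_matrix, constraints=[{"SPO", "NOPE"}],
                           generations=2000)

    def test_reproducible_given_seed(self, reported_matrix):
        a = mcmc_posterior(reported_matrix, generations=5000, seed=42, outgroup="OUT")
        b = mcmc_posterior(reported_matrix, generations=5000, seed=42, outgroup="OUT")
        assert a.clade_posterior == b.clade_posterior
        assert a.map_tree == b.map_tree

    def test_no_signal_matrix_recovers_uniform_topology_prior(self):
        # all-missing characters carry no likelihood signal, so every clade's
        # posterior equals its frequency among the 15 rooted topologies (0.2)
        taxa = ["OUT", "A", "B", "C", "D"]
        m = matrix_from_rows({t: "????" for t in taxa})
        post = mcmc_posterior(m, generations=60_000, seed=8, outgroup="OUT")
        for clade, p in post.clade_posterior.items():
            if len(clade) in (2, 3) and len(clade) < 4:
                assert p == pytest.approx(0.2, abs=0.05)

    def test_constraint_is_honoured(self, reported_matrix):
        post = mcmc_posterior(reported_matrix, generations=5000, seed=1,
                              outgroup="OUT", constraints=[{"CNI", "BIL"}])
        assert post.clade({"CNI", "BIL"}) == 1.0
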