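"""Tree inference from fusion characters.

Two engines operate on the 3-state fusion characters (0 separate, 1 fused
unmixed, 2 fused and mixed, ? missing):

* **Sankoff parsimony** with an asymmetric step matrix.  The default costs
  make fusion (0->1), fission (1->0) and mixing (1->2) each one step, allow
  fusion-with-mixing in a single edge (0->2 = 2 steps), and forbid unmixing
  (2->0, 2->1 = infinity) — the derived mixed state is Dollo-like.

* **Bayesian MCMC** under a continuous-time 3-state Markov model with free
  fusion, fission and mixing rates and the unmixing rates fixed at 0 by
  default, so state 2 is absorbing.  The root (outgroup attachment) state is
  fixed to 0 (separate) by default.  Metropolis–Hastings moves update branch
  lengths, rates, and topology (rooted nearest-neighbour interchanges with
  the outgroup pinned at the root); clade posteriors are computed from
  post-burn-in samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .characters import CharacterMatrix
from .errors import InputError

INF = float("inf")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """A rooted tree node; ``length`` is the branch above the node (Myr or
    arbitrary units)."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None,
                 children: list["Node"] | None = None,
                 length: float = 1.0):
        self.name = name
        self.children = children or []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def postorder(self) -> list["Node"]:
        out = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out

    def copy(self) -> "Node":
        return Node(self.name, [c.copy() for c in self.children], self.length)

    def newick(self, lengths: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in sorted(
                    n.children, key=lambda x: min(x.leaf_names()))) + ")"
                if n.name:
                    s += n.name
            if lengths and n is not self:
                s += f":{n.length:g}"
            return s
        return fmt(self) + ";"

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets below each internal node (excluding the root's full
        set and leaf singletons)."""
        full = self.leaf_names()
        out = set()
        for n in self.postorder():
            if not n.is_leaf and n is not self:
                s = n.leaf_names()
                if s != full and len(s) > 1:
                    out.add(s)
        return out


def tree_from_newick(text: str) -> Node:
    """Parse a Newick string (via dendropy) into a :class:`Node` tree."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")
    def convert(dnode) -> Node:
        n = Node(
            name=dnode.taxon.label if dnode.taxon else dnode.label,
            length=dnode.edge.length if dnode.edge.length is not None else 1.0,
        )
        n.children = [convert(c) for c in dnode.child_nodes()]
        return n
    return convert(dtree.seed_node)


def enumerate_topologies(taxa: Sequence[str], outgroup: str) -> list[Node]:
    """All rooted-by-outgroup binary topologies, each exactly once.

    The root has two children: the outgroup leaf and the ingroup subtree.
    For k ingroup leaves there are (2k-3)!! topologies; the exhaustive
    regime is capped at 9 taxa.
    """
    taxa = list(taxa)
    if outgroup not in taxa:
        raise InputError(f"outgroup {outgroup!r} not in taxa")
    if not (3 <= len(taxa) <= 9):
        raise InputError(
            f"{len(taxa)} taxa outside the exhaustive regime (3..9); use MCMC"
        )
    ingroup = [t for t in taxa if t != outgroup]

    def insert_all(tree: Node, leaf_name: str) -> list[Node]:
        """Insert a new leaf on every edge of `tree` (including above the
        root), returning new trees."""
        results = []
        n_nodes = len(tree.postorder())
        for i in range(n_nodes):  # attach above node i (postorder index)
            t = tree.copy()
            nodes = t.postorder()
            target = nodes[i]
            new_leaf = Node(leaf_name)
            joint = Node(children=[target, new_leaf])
            if target is t:
                results.append(joint)
            else:
                parent = next(n for n in t.postorder() if target in n.children)
                parent.children[parent.children.index(target)] = joint
                results.append(t)
        return results

    trees = [Node(ingroup[0])]
    for name in ingroup[1:]:
        trees = [t2 for t in trees for t2 in insert_all(t, name)]
    return [Node(children=[Node(outgroup), t]) for t in trees]


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepMatrix:
    """3x3 per-edge step costs over states (0, 1, 2); INF entries forbid the
    transition.  Entries are used as-is (no shortest-path closure): a cost
    for 0->2 in a single edge must be given explicitly if desired."""

    cost: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        c = self.cost
        if len(c) != 3 or any(len(r) != 3 for r in c):
            raise InputError("step matrix must be 3x3")
        if any(c[i][i] != 0 for i in range(3)):
            raise InputError("step matrix diagonal must be zero")
        if any(c[i][j] < 0 for i in range(3) for j in range(3)):
            raise InputError("step costs must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(self.cost, dtype=float)


#: fusion/fission one step each, mixing one step, fusion-with-mixing on a
#: single edge two steps, unmixing forbidden.
DEFAULT_STEPS = StepMatrix(((0.0, 1.0, 2.0), (1.0, 0.0, 1.0), (INF, INF, 0.0)))

_STATE_CODE = {"0": 0, "1": 1, "2": 2, "?": -1}


def _state_array(matrix: CharacterMatrix) -> np.ndarray:
    """(n_taxa, n_chars) int8 array, -1 for missing."""
    return np.array(
        [[_STATE_CODE[matrix.state(t, j)] for j in range(len(matrix))]
         for t in matrix.taxa],
        dtype=np.int8,
    )


def sankoff_cost(
    matrix: CharacterMatrix,
    tree: Node,
    steps: StepMatrix = DEFAULT_STEPS,
    fix_root_state: int | None = None,
) -> tuple[float, list[float]]:
    """Minimum total step cost of the matrix on the tree (plus per-character
    costs) by the Sankoff dynamic programme.

    Missing states ('?') cost 0 in every leaf state.  The root state is free
    (minimum over states) unless ``fix_root_state`` pins it (0 = ancestral
    separate).
    """
    leaf_names = tree.leaf_names()
    if leaf_names != frozenset(matrix.taxa):
        raise InputError(
            f"tree taxa {sorted(leaf_names)} != matrix taxa {sorted(matrix.taxa)}"
        )
    cost = steps.as_array()
    states = _state_array(matrix)
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    n_chars = len(matrix)

    def dp(node: Node) -> np.ndarray:  # (n_chars, 3)
        if node.is_leaf:
            s = states[taxon_row[node.name]]  # (n_chars,)
            out = np.full((n_chars, 3), INF)
            missing = s < 0
            out[missing, :] = 0.0
            idx = np.nonzero(~missing)[0]
            out[idx, s[idx]] = 0.0
            return out
        total = np.zeros((n_chars, 3))
        for child in node.children:
            sub = dp(child)  # (n_chars, 3)
            # min over child state t of cost[s, t] + sub[:, t]
            with np.errstate(invalid="ignore"):
                comp = cost[None, :, :] + sub[:, None, :]
            comp = np.where(np.isnan(comp), INF, comp)
            total = total + comp.min(axis=2)
        return total

    root_costs = dp(tree)
    if fix_root_state is not None:
        per_char = root_costs[:, fix_root_state]
    else:
        per_char = root_costs.min(axis=1)
    return float(per_char.sum()), [float(v) for v in per_char]


def parsimony_search(
    matrix: CharacterMatrix,
    outgroup: str,
    steps: StepMatrix = DEFAULT_STEPS,
    fix_root_state: int | None = None,
) -> list[tuple[Node, float]]:
    """Score all rooted topologies exhaustively; returns (tree, cost) sorted
    by cost ascending."""
    scored = [
        (t, sankoff_cost(matrix, t, steps, fix_root_state)[0])
        for t in enumerate_topologies(matrix.taxa, outgroup)
    ]
    return sorted(scored, key=lambda tc: (tc[1], tc[0].newick(lengths=False)))


# ---------------------------------------------------------------------------
# Likelihood under the irreversible 3-state CTMC
# ---------------------------------------------------------------------------

@dataclass
class RateModel:
    """Rates per unit branch length: fusion 0->1, fission 1->0, mixing 1->2,
    and unmixing 2->1 and 2->0 (epsilon; 0 = strictly irreversible)."""

    fusion: float = 1.0
    fission: float = 1.0
    mixing: float = 1.0
    unmixing: float = 0.0

    def q_matrix(self) -> np.ndarray:
        a, b, c, e = self.fusion, self.fission, self.mixing, self.unmixing
        return np.array(
            [[-a, a, 0.0],
             [b, -(b + c), c],
             [e, e, -2 * e]]
        )


def transition_matrices(model: RateModel, lengths: np.ndarray) -> np.ndarray:
    """P(t) for each branch length; shape (n_edges, 3, 3).

    With unmixing = 0 state 2 is absorbing and the transient 2x2 block is
    exponentiated in closed form via its (real) eigenvalues; otherwise a
    generic matrix exponential is used per edge.
    """
    lengths = np.asarray(lengths, dtype=float)
    if model.unmixing != 0.0:
        from scipy.linalg import expm

        q = model.q_matrix()
        return np.stack([expm(q * t) for t in lengths])
    a, b, c = model.fusion, model.fission, model.mixing
    m = np.array([[-a, a], [b, -(b + c)]])
    tr = -(a + b + c)
    det = a * c
    disc = max(tr * tr - 4 * det, 0.0)
    sq = math.sqrt(disc)
    l1, l2 = (tr + sq) / 2.0, (tr - sq) / 2.0
    n = lengths.shape[0]
    p = np.zeros((n, 3, 3))
    if sq < 1e-12:
        # (near-)degenerate eigenvalues: expm(Mt) = e^{l t}(I + (M - l I) t)
        el = np.exp(l1 * lengths)[:, None, None]
        block = el * (np.eye(2)[None] + (m - l1 * np.eye(2))[None] * lengths[:, None, None])
    else:
        e1 = np.exp(l1 * lengths)[:, None, None]
        e2 = np.exp(l2 * lengths)[:, None, None]
        a1 = (m - l2 * np.eye(2)) / (l1 - l2)
        a2 = (m - l1 * np.eye(2)) / (l2 - l1)
        block = e1 * a1[None] + e2 * a2[None]
    block = np.clip(block, 0.0, 1.0)
    p[:, :2, :2] = block
    p[:, 0, 2] = 1.0 - block[:, 0, :].sum(axis=1)
    p[:, 1, 2] = 1.0 - block[:, 1, :].sum(axis=1)
    p[:, 2, 2] = 1.0
    np.clip(p, 0.0, 1.0, out=p)
    return p


class _TreeArrays:
    """Flattened postorder representation for fast pruning."""

    def __init__(self, tree: Node, taxa: Sequence[str]):
        nodes = tree.postorder()
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n = len(nodes)
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in nodes
        ]
        self.lengths = np.array([n.length for n in nodes], dtype=float)
        self.leaf_row = [
            taxa.index(n.name) if n.is_leaf else -1 for n in nodes
        ]
        self.root = self.n - 1


def _prune(
    states: np.ndarray,
    arrays: _TreeArrays,
    pmats: np.ndarray,
    root_state: int,
) -> float:
    """Pruning pass given precomputed per-edge transition matrices."""
    n_chars = states.shape[1]
    partials = np.empty((arrays.n, n_chars, 3))
    for i in range(arrays.n):
        kids = arrays.children[i]
        if not kids:
            row = states[arrays.leaf_row[i]]
            part = np.zeros((n_chars, 3))
            part[row < 0, :] = 1.0
            idx = np.nonzero(row >= 0)[0]
            part[idx, row[idx]] = 1.0
            partials[i] = part
        else:
            acc = np.ones((n_chars, 3))
            for k in kids:
                acc *= partials[k] @ pmats[k].T
            partials[i] = acc
    char_lik = partials[arrays.root][:, root_state]
    if np.any(char_lik <= 0.0):
        return -INF
    return float(np.log(char_lik).sum())


def _log_likelihood(
    states: np.ndarray,  # (n_taxa, n_chars), -1 missing
    arrays: _TreeArrays,
    model: RateModel,
    root_state: int = 0,
) -> float:
    """Felsenstein pruning log-likelihood; -inf when any character has
    probability exactly 0 (e.g. an irreversibility violation)."""
    pmats = transition_matrices(model, arrays.lengths)
    return _prune(states, arrays, pmats, root_state)


def log_likelihood(
    matrix: CharacterMatrix,
    tree: Node,
    model: RateModel,
    root_state: int = 0,
) -> float:
    """Log-likelihood of the character matrix on a tree under the 3-state
    model, with the root (outgroup attachment) state fixed."""
    if tree.leaf_names() != frozenset(matrix.taxa):
        raise InputError("tree taxa do not match matrix taxa")
    return _log_likelihood(
        _state_array(matrix), _TreeArrays(tree, matrix.taxa), model, root_state
    )


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    clade_posterior: dict[frozenset[str], float]
    generations: int
    burn_in_fraction: float
    seed: int
    acceptance: dict[str, float]
    n_samples: int
    map_tree: str
    n_zero_likelihood: int = 0

    def clade(self, taxa: Iterable[str]) -> float:
        return self.clade_posterior.get(frozenset(taxa), 0.0)


def _nni_moves(tree: Node) -> list[tuple[Node, Node, Node]]:
    """Eligible rooted-NNI triples (parent u, internal child v, grandchild x):
    swap x with v's sibling.  Moves at the tree root are excluded so the
    outgroup stays pinned as the root's direct child."""
    moves = []
    for u in tree.postorder():
        if u.is_leaf or u is tree:
            continue
        for v in u.children:
            if v.is_leaf:
                continue
            for x in v.children:
                moves.append((u, v, x))
    return moves


def _apply_nni(u: Node, v: Node, x: Node) -> None:
    w = u.children[0] if u.children[1] is v else u.children[1]
    u.children[u.children.index(w)] = x
    v.children[v.children.index(x)] = w


def _satisfies(tree: Node, constraints: Sequence[frozenset[str]]) -> bool:
    clades = tree.clades()
    return all(c in clades for c in constraints)


def mcmc_posterior(
    matrix: CharacterMatrix,
    model: RateModel | None = None,
    constraints: Sequence[Iterable[str]] | None = None,
    generations: int = 100_000,
    burn_in_fraction: float = 0.25,
    seed: int = 0,
    outgroup: str | None = None,
    root_state: int = 0,
    sample_every: int = 10,
    branch_length_prior_mean: float = 0.1,
    rate_prior_mean: float = 1.0,
) -> PosteriorSummary:
    """Metropolis–Hastings sampling of topology, branch lengths, and rates.

    Priors: exponential(mean ``rate_prior_mean``) on the three free rates,
    exponential(mean ``branch_length_prior_mean``) on branch lengths, uniform
    over rooted-by-outgroup topologies.  The unmixing rate stays at the value
    in ``model`` (default 0: irreversible).  Topologies assigning zero
    likelihood are proposed and rejected, never errors.  Single-threaded and
    reproducible bit-for-bit given (seed, generations).
    """
    if generations < 1000:
        raise InputError("generations must be >= 1000")
    if len(matrix) == 0:
        raise InputError("empty character matrix")
    taxa = list(matrix.taxa)
    outgroup = outgroup or taxa[0]
    if outgroup not in taxa:
        raise InputError(f"outgroup {outgroup!r} not in matrix taxa")
    constraint_sets = [frozenset(c) for c in (constraints or [])]
    for c in constraint_sets:
        if not c <= set(taxa):
            raise InputError(f"constraint {sorted(c)} contains unknown taxa")
    model = model or RateModel()
    rng = np.random.default_rng(seed)
    states = _state_array(matrix)
    bl_rate = 1.0 / branch_length_prior_mean
    rate_rate = 1.0 / rate_prior_mean

    # initial state: first constraint-compatible topology with finite
    # likelihood; random branch lengths from the prior
    if len(taxa) <= 9:
        candidates = enumerate_topologies(taxa, outgroup)
        candidates = [candidates[i] for i in rng.permutation(len(candidates))]
    else:  # too many taxa to enumerate: random sequential-insertion trees
        candidates = []
        ingroup = [t for t in taxa if t != outgroup]
        for _ in range(64):
            sub = Node(ingroup[0])
            for name in ingroup[1:]:
                nodes = sub.postorder()
                target = nodes[rng.integers(len(nodes))]
                joint = Node(children=[target, Node(name)])
                if target is sub:
                    sub = joint
                else:
                    parent = next(n for n in sub.postorder()
                                  if target in n.children)
                    parent.children[parent.children.index(target)] = joint
            candidates.append(Node(children=[Node(outgroup), sub]))
    tree = None
    for cand in candidates:
        if constraint_sets and not _satisfies(cand, constraint_sets):
            continue
        for n in cand.postorder():
            n.length = float(rng.exponential(branch_length_prior_mean))
        if _log_likelihood(states, _TreeArrays(cand, taxa), model, root_state) > -INF:
            tree = cand
            break
    if tree is None:
        raise InputError("no constraint-compatible topology has positive likelihood")

    rates = np.array([model.fusion, model.fission, model.mixing])

    def posterior_terms(t: Node, r: np.ndarray) -> tuple[float, float]:
        mdl = RateModel(r[0], r[1], r[2], model.unmixing)
        ll = _log_likelihood(states, _TreeArrays(t, taxa), mdl, root_state)
        lengths = [n.length for n in t.postorder() if n is not t]
        lp = sum(-bl_rate * l for l in lengths) + sum(-rate_rate * x for x in r)
        return ll, lp

    loglik, logprior = posterior_terms(tree, rates)
    burn_in = int(generations * burn_in_fraction)
    clade_counts: dict[frozenset[str], int] = {}
    topo_counts: dict[str, int] = {}
    n_samples = 0
    n_zero = 0
    proposed = {"branch": 0, "rate": 0, "nni": 0, "jump": 0, "gibbs": 0}
    accepted = {"branch": 0, "rate": 0, "nni": 0, "jump": 0, "gibbs": 0}
    best = (loglik + logprior, tree.newick())

    nodes_cache = [n for n in tree.postorder() if n is not tree]
    # topology pool for the independence jump move (small-taxon regime only)
    if len(taxa) <= 9:
        jump_pool = [t for t in enumerate_topologies(taxa, outgroup)
                     if not constraint_sets or _satisfies(t, constraint_sets)]
    else:
        jump_pool = []

    # move mixture: in the enumerable regime a Gibbs topology move (exact
    # conditional over all rooted topologies, branch lengths carried by
    # postorder position) plus an independence refresh decorrelate topology
    # and rates; NNI keeps the sampler general for larger trees
    gibbs_cut = 0.75 if jump_pool else 1.1
    jump_cut = 0.6 if jump_pool else 1.1
    pool_nodes = [[n for n in t.postorder() if n is not t] for t in jump_pool]
    pool_arrays = [_TreeArrays(t, taxa) for t in jump_pool]
    for gen in range(generations):
        u = rng.random()
        if gibbs_cut <= u:
            # Gibbs: sample topology from p(T | lengths, rates)
            kind = "gibbs"
            proposed["gibbs"] += 1
            current_lengths = [n.length for n in nodes_cache]
            mdl = RateModel(rates[0], rates[1], rates[2], model.unmixing)
            # lengths are carried by postorder position, so the per-edge
            # transition matrices are shared by every candidate topology
            lvec = np.append(np.asarray(current_lengths), 0.0)
            pmats = transition_matrices(mdl, lvec)
            lls = np.empty(len(jump_pool))
            for i, (t, tn) in enumerate(zip(jump_pool, pool_nodes)):
                for n, l in zip(tn, current_lengths):
                    n.length = l
                lls[i] = _prune(states, pool_arrays[i], pmats, root_state)
            if not np.isfinite(lls.max()):
                continue
            w = np.exp(lls - lls.max())
            w /= w.sum()
            j = int(rng.choice(len(jump_pool), p=w))
            tree = jump_pool[j].copy()
            nodes_cache = [n for n in tree.postorder() if n is not tree]
            loglik = float(lls[j])
            accepted["gibbs"] += 1
            if loglik + logprior > best[0]:
                best = (loglik + logprior, tree.newick())
            if gen >= burn_in and (gen - burn_in) % sample_every == 0:
                n_samples += 1
                for clade in tree.clades():
                    clade_counts[clade] = clade_counts.get(clade, 0) + 1
                topo = tree.newick(lengths=False)
                topo_counts[topo] = topo_counts.get(topo, 0) + 1
            continue
        if jump_cut <= u:
            # global topology move: uniform topology with either (a) branch
            # lengths carried over by postorder position (symmetric proposal;
            # Hastings 1) or (b) fresh lengths from the prior (independence
            # proposal; Hastings = prior ratio).  Either way the acceptance
            # ratio reduces to the likelihood ratio.
            kind = "jump"
            cand = jump_pool[rng.integers(len(jump_pool))].copy()
            cand_nodes = [n for n in cand.postorder() if n is not cand]
            u2 = rng.random()
            if u2 < 0.4:
                # carry branch lengths over by postorder position
                current_lengths = [n.length for n in nodes_cache]
                for n, l in zip(cand_nodes, current_lengths):
                    n.length = l
            else:
                for n in cand_nodes:
                    n.length = float(rng.exponential(branch_length_prior_mean))
            cand_rates = rates
            if u2 >= 0.7:
                cand_rates = rng.exponential(rate_prior_mean, size=3)
            new_ll, new_lp = posterior_terms(cand, cand_rates)
            proposed[kind] += 1
            if new_ll == -INF:
                n_zero += 1
                accept = False
            else:
                la = new_ll - loglik
                accept = la >= 0 or rng.random() < math.exp(la)
            if accept:
                tree = cand
                rates = cand_rates
                loglik, logprior = new_ll, new_lp
                accepted[kind] += 1
                nodes_cache = cand_nodes
                if loglik + logprior > best[0]:
                    best = (loglik + logprior, tree.newick())
            if gen >= burn_in and (gen - burn_in) % sample_every == 0:
                n_samples += 1
                for clade in tree.clades():
                    clade_counts[clade] = clade_counts.get(clade, 0) + 1
                topo = tree.newick(lengths=False)
                topo_counts[topo] = topo_counts.get(topo, 0) + 1
            continue
        u = u / jump_cut  # rescale to [0,1) over the local moves
        if u < 0.5:
            kind = "branch"
            node = nodes_cache[rng.integers(len(nodes_cache))]
            old = node.length
            mult = math.exp(0.5 * (rng.random() - 0.5) * 2)
            node.length = old * mult
            hastings = math.log(mult)
            new_ll, new_lp = posterior_terms(tree, rates)
            revert = lambda: setattr(node, "length", old)
        elif u < 0.7:
            kind = "rate"
            i = int(rng.integers(3))
            old_r = rates[i]
            mult = math.exp(0.5 * (rng.random() - 0.5) * 2)
            rates = rates.copy()
            rates[i] = old_r * mult
            hastings = math.log(mult)
            new_ll, new_lp = posterior_terms(tree, rates)
            def revert(i=i, old_r=old_r):
                rates[i] = old_r
        else:
            kind = "nni"
            moves = _nni_moves(tree)
            if not moves:
                continue
            mu, mv, mx = moves[rng.integers(len(moves))]
            mw = mu.children[0] if mu.children[1] is mv else mu.children[1]
            _apply_nni(mu, mv, mx)  # swaps mx (in v) with sibling mw (in u)
            if constraint_sets and not _satisfies(tree, constraint_sets):
                _apply_nni(mu, mv, mw)  # undo
                proposed[kind] += 1
                continue
            n_moves_new = len(_nni_moves(tree))
            hastings = math.log(len(moves)) - math.log(n_moves_new)
            new_ll, new_lp = posterior_terms(tree, rates)
            def revert(mu=mu, mv=mv, mw=mw):
                _apply_nni(mu, mv, mw)
        proposed[kind] += 1
        if new_ll == -INF:
            n_zero += 1
            log_alpha = -INF
        else:
            log_alpha = (new_ll + new_lp) - (loglik + logprior) + hastings
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            loglik, logprior = new_ll, new_lp
            accepted[kind] += 1
            if kind == "nni":
                nodes_cache = [n for n in tree.postorder() if n is not tree]
            if loglik + logprior > best[0]:
                best = (loglik + logprior, tree.newick())
        else:
            revert()
            if kind == "nni":
                nodes_cache = [n for n in tree.postorder() if n is not tree]
        if gen >= burn_in and (gen - burn_in) % sample_every == 0:
            n_samples += 1
            for clade in tree.clades():
                clade_counts[clade] = clade_counts.get(clade, 0) + 1
            topo = tree.newick(lengths=False)
            topo_counts[topo] = topo_counts.get(topo, 0) + 1

    acc = {
        k: (accepted[k] / proposed[k] if proposed[k] else 0.0) for k in proposed
    }
    posts = {c: n / n_samples for c, n in clade_counts.items()}
    map_topo = max(topo_counts.items(), key=lambda kv: kv[1])[0] if topo_counts else ""
    return PosteriorSummary(
        posts, generations, burn_in_fraction, seed, acc, n_samples, map_topo, n_zero
    )
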