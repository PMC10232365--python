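"""Genome evolution simulator with a known event log (ground truth).

A root genome (``n_chromosomes`` x ``genes_per_chromosome`` opaque gene ids)
evolves along a Newick tree whose branch lengths are in Myr.  Event kinds:

* ``translocation`` — one gene moves to a uniform random position on another
  chromosome.  Each gene translocates with probability 1 - exp(-lambda * t)
  over a branch of t Myr; the default lambda encodes the empirical animal
  rate of ~1% of genes per 40 Myr (lambda = -ln(0.99)/40).
* ``fusion`` — two chromosomes concatenate (reversible while unmixed).
* ``fission`` — a chromosome splits at a uniform internal boundary.
* ``mixing`` — riffle-style reordering within a chromosome (k interleavings,
  default 3, so partial mixing is producible; k large approximates a full
  shuffle).
* ``fusion_with_mixing`` — fusion immediately followed by mixing of the
  fused chromosome; essentially irreversible.
* ``gene_loss`` / ``gene_gain`` — single-gene deletion / insertion.

Stochastic event counts are Poisson in (rate x branch length); forced events
are applied at the branch midpoint.  Every sampled event is recorded with
concrete parameters, so replaying the log from the root genome reproduces
each leaf genome exactly.  Gene ids survive all events, giving
identity-preserving orthology; leaf genomes carry species-prefixed ids
(``SP.g00042``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, ReplayError
from .genome import GeneLocus, Genome, SimilarityHits, write_gene_map, write_hits
from .phylo import Node, tree_from_newick

#: per-gene per-Myr translocation rate equivalent to 1% of genes per 40 Myr
TRANSLOCATION_RATE = -math.log(0.99) / 40.0

EVENT_KINDS = (
    "translocation", "fusion", "fusion_with_mixing", "fission",
    "mixing", "gene_loss", "gene_gain",
)


@dataclass
class SimRates:
    """Event rates.  Translocation is per gene per Myr; the others are per
    genome per Myr (Poisson intensities).  Structural rates default to 0 —
    rare fusion/fission/mixing events are placed explicitly as forced events
    in controlled experiments."""

    translocation: float = TRANSLOCATION_RATE
    fusion: float = 0.0
    fission: float = 0.0
    mixing: float = 0.0
    fusion_with_mixing: float = 0.0
    gene_loss: float = 0.0
    gene_gain: float = 0.0


@dataclass(frozen=True)
class SimEvent:
    branch: str  # id of the edge (= name of the child node)
    kind: str
    params: tuple[tuple[str, object], ...]

    @classmethod
    def make(cls, branch: str, kind: str, **params) -> "SimEvent":
        if kind not in EVENT_KINDS:
            raise InputError(f"unknown event kind {kind!r}")
        return cls(branch, kind, tuple(sorted(params.items())))

    @property
    def p(self) -> dict:
        return dict(self.params)


class _WorkingGenome:
    """Mutable chromosome -> ordered gene-id list representation."""

    def __init__(self, chroms: dict[str, list[str]]):
        self.chroms = {c: list(g) for c, g in chroms.items()}

    def copy(self) -> "_WorkingGenome":
        return _WorkingGenome(self.chroms)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chroms.values())

    def locate(self, gene: str) -> tuple[str, int]:
        for c, genes in self.chroms.items():
            try:
                return c, genes.index(gene)
            except ValueError:
                continue
        raise KeyError(gene)

    def apply(self, event: SimEvent, index: int = -1) -> None:
        p = event.p
        try:
            if event.kind == "translocation":
                chrom, pos = self.locate(p["gene"])
                self.chroms[chrom].pop(pos)
                self.chroms[p["to_chrom"]].insert(p["at"], p["gene"])
            elif event.kind in ("fusion", "fusion_with_mixing"):
                a, b = p["chrom_a"], p["chrom_b"]
                merged = self.chroms.pop(a) + self.chroms.pop(b)
                if event.kind == "fusion_with_mixing":
                    merged = [merged[i] for i in p["order"]]
                self.chroms[f"{a}+{b}"] = merged
            elif event.kind == "fission":
                c, at = p["chrom"], p["at"]
                genes = self.chroms.pop(c)
                if not (1 <= at <= len(genes) - 1):
                    raise KeyError(f"bad split point {at} for {c}")
                self.chroms[f"{c}_p1"] = genes[:at]
                self.chroms[f"{c}_p2"] = genes[at:]
            elif event.kind == "mixing":
                c = p["chrom"]
                genes = self.chroms[c]
                self.chroms[c] = [genes[i] for i in p["order"]]
            elif event.kind == "gene_loss":
                chrom, pos = self.locate(p["gene"])
                self.chroms[chrom].pop(pos)
            elif event.kind == "gene_gain":
                self.chroms[p["chrom"]].insert(p["at"], p["gene"])
            else:
                raise KeyError(event.kind)
        except (KeyError, ValueError) as exc:
            raise ReplayError(
                f"{event.kind} with {p} inapplicable ({exc})", index
            ) from exc

    def to_genome(self, species_id: str, prefix: bool = False) -> Genome:
        loci = []
        for chrom, genes in self.chroms.items():
            for i, g in enumerate(genes):
                gid = f"{species_id}.{g}" if prefix else g
                start = i * 1000 + 1
                loci.append(GeneLocus(gid, chrom, start, start + 500, "+"))
        return Genome.from_loci(species_id, loci)


@dataclass
class SimTruth:
    """Simulator ground truth: the tree, the per-branch event log, the leaf
    genomes (species-prefixed gene ids), and identity orthology on base
    gene ids."""

    tree: Node
    events: list[SimEvent]
    root_genome: Genome
    leaf_genomes: dict[str, Genome]
    seed: int
    orthology: dict[str, dict[str, str]] = field(default_factory=dict)
    # taxon -> {base gene id -> leaf gene id}

    def events_for(self, taxon: str) -> list[SimEvent]:
        """Events along the root -> taxon path, in application order."""
        path: list[str] = []

        def walk(node: Node, trail: list[str]) -> bool:
            if node.is_leaf and node.name == taxon:
                path.extend(trail)
                return True
            return any(walk(c, trail + [c.name]) for c in node.children)

        if not walk(self.tree, []):
            raise InputError(f"taxon {taxon!r} not in tree")
        branch_set = {b for b in path}
        ordered = [e for e in self.events if e.branch in branch_set]
        # events are stored in simulation (preorder) order, which matches
        # the root->leaf application order along any single path
        return ordered

    def replay(self, taxon: str) -> Genome:
        g = replay_events(self.root_genome, self.events_for(taxon))
        work = _WorkingGenome({c: [l.gene_id for l in loci]
                               for c, loci in g.chromosomes.items()})
        return work.to_genome(taxon, prefix=True)


def replay_events(root_genome: Genome, events: Sequence[SimEvent]) -> Genome:
    """Deterministically re-apply an event list to a genome."""
    work = _WorkingGenome(
        {c: [l.gene_id for l in loci] for c, loci in root_genome.chromosomes.items()}
    )
    for i, ev in enumerate(events):
        work.apply(ev, i)
    return work.to_genome(root_genome.species_id)


def _riffle(n: int, rng: np.random.Generator, k: int = 3) -> list[int]:
    """Composition of k Gilbert–Shannon–Reeds riffle interleavings of 0..n-1."""
    order = list(range(n))
    for _ in range(k):
        cut = int(rng.binomial(n, 0.5))
        left, right = order[:cut], order[cut:]
        merged = []
        while left and right:
            if rng.random() < len(left) / (len(left) + len(right)):
                merged.append(left.pop(0))
            else:
                merged.append(right.pop(0))
        merged.extend(left or right)
        order = merged
    return order


def _name_internal(node: Node) -> None:
    for n in node.postorder():
        if not n.is_leaf and not n.name:
            n.name = "mrca_" + "_".join(sorted(n.leaf_names()))


def simulate_evolution(
    tree: str | Node,
    root_spec: tuple[int, int] = (15, 400),
    rates: SimRates | None = None,
    forced_events: Sequence[tuple[str, str, Mapping]] | None = None,
    seed: int = 0,
    riffle_k: int = 3,
) -> SimTruth:
    """Evolve a genome along a tree, returning the full ground truth.

    ``tree`` is a Newick string (branch lengths in Myr) or a :class:`Node`.
    ``root_spec`` = (n_chromosomes, genes_per_chromosome); the default
    15 x 400 gives a 6,000-gene chromosome-scale genome.  ``forced_events``
    entries are (branch_id, kind, params); the branch id is the name of the
    edge's child node (internal nodes are auto-named ``mrca_<leaves>``).
    Randomized parameters (mixing orders, split points) left out of a forced
    event's params are sampled and recorded concretely.
    """
    if isinstance(tree, str):
        tree = tree_from_newick(tree)
    _name_internal(tree)
    rates = rates or SimRates()
    for f in vars(rates).values():
        if f < 0:
            raise InputError("rates must be >= 0")
    n_chrom, n_per = root_spec
    width = len(str(n_chrom * n_per))
    root = _WorkingGenome({
        f"anc{c + 1}": [f"g{c * n_per + i + 1:0{width}d}" for i in range(n_per)]
        for c in range(n_chrom)
    })
    rng = np.random.default_rng(seed)
    forced_by_branch: dict[str, list[tuple[str, Mapping]]] = {}
    known_branches = {n.name for n in tree.postorder() if n is not tree}
    for branch, kind, params in forced_events or ():
        if branch not in known_branches:
            raise InputError(f"forced event on unknown branch {branch!r}")
        forced_by_branch.setdefault(branch, []).append((kind, dict(params)))

    events: list[SimEvent] = []
    leaf_genomes: dict[str, Genome] = {}

    def sample_background(work: _WorkingGenome, branch: str, t: float) -> None:
        if t <= 0:
            return
        # translocations: per-gene exponential waiting, cumulative over t
        p_move = 1.0 - math.exp(-rates.translocation * t)
        genes = [g for c in sorted(work.chroms) for g in work.chroms[c]]
        if p_move > 0 and len(work.chroms) > 1:
            n_move = int(rng.binomial(len(genes), p_move))
            movers = rng.choice(len(genes), size=n_move, replace=False)
            for gi in sorted(int(i) for i in movers):
                gene = genes[gi]
                try:
                    src, _ = work.locate(gene)
                except KeyError:
                    continue
                others = [c for c in sorted(work.chroms) if c != src]
                if not others:
                    continue
                dest = others[int(rng.integers(len(others)))]
                at = int(rng.integers(len(work.chroms[dest]) + 1))
                ev = SimEvent.make(branch, "translocation",
                                   gene=gene, to_chrom=dest, at=at)
                work.apply(ev)
                events.append(ev)
        for kind, rate in (
            ("fusion", rates.fusion),
            ("fission", rates.fission),
            ("mixing", rates.mixing),
            ("fusion_with_mixing", rates.fusion_with_mixing),
            ("gene_loss", rates.gene_loss),
            ("gene_gain", rates.gene_gain),
        ):
            if rate <= 0:
                continue
            for _ in range(int(rng.poisson(rate * t))):
                ev = _sample_event(work, branch, kind)
                if ev is not None:
                    work.apply(ev)
                    events.append(ev)

    gain_counter = [0]

    def _sample_event(work: _WorkingGenome, branch: str, kind: str,
                      params: dict | None = None) -> SimEvent | None:
        p = dict(params or {})
        chroms = sorted(work.chroms)
        if kind in ("fusion", "fusion_with_mixing"):
            if "chrom_a" not in p:
                if len(chroms) < 2:
                    return None
                i, j = rng.choice(len(chroms), size=2, replace=False)
                p["chrom_a"], p["chrom_b"] = chroms[int(i)], chroms[int(j)]
            for c in (p["chrom_a"], p["chrom_b"]):
                if c not in work.chroms:
                    raise InputError(f"forced event references absent chromosome {c!r}")
            if kind == "fusion_with_mixing" and "order" not in p:
                n = len(work.chroms[p["chrom_a"]]) + len(work.chroms[p["chrom_b"]])
                p["order"] = _riffle(n, rng, riffle_k)
        elif kind == "fission":
            if "chrom" not in p:
                eligible = [c for c in chroms if len(work.chroms[c]) >= 2]
                if not eligible:
                    return None
                p["chrom"] = eligible[int(rng.integers(len(eligible)))]
            if p["chrom"] not in work.chroms:
                raise InputError(f"forced event references absent chromosome {p['chrom']!r}")
            if "at" not in p:
                p["at"] = int(rng.integers(1, len(work.chroms[p["chrom"]])))
        elif kind == "mixing":
            if "chrom" not in p:
                p["chrom"] = chroms[int(rng.integers(len(chroms)))]
            if p["chrom"] not in work.chroms:
                raise InputError(f"forced event references absent chromosome {p['chrom']!r}")
            if "order" not in p:
                p["order"] = _riffle(len(work.chroms[p["chrom"]]), rng, riffle_k)
        elif kind == "gene_loss":
            if "gene" not in p:
                genes = [g for c in chroms for g in work.chroms[c]]
                p["gene"] = genes[int(rng.integers(len(genes)))]
        elif kind == "gene_gain":
            if "gene" not in p:
                gain_counter[0] += 1
                p["gene"] = f"new{gain_counter[0]:05d}"
            if "chrom" not in p:
                p["chrom"] = chroms[int(rng.integers(len(chroms)))]
            if "at" not in p:
                p["at"] = int(rng.integers(len(work.chroms[p["chrom"]]) + 1))
        elif kind == "translocation":
            if p["to_chrom"] not in work.chroms:
                raise InputError(
                    f"forced event references absent chromosome {p['to_chrom']!r}")
            if "at" not in p:
                p["at"] = int(rng.integers(len(work.chroms[p["to_chrom"]]) + 1))
        return SimEvent.make(branch, kind, **p)

    def descend(node: Node, work: _WorkingGenome) -> None:
        for child in node.children:
            sub = work.copy()
            branch = child.name
            half = child.length / 2.0
            sample_background(sub, branch, half)
            for kind, params in forced_by_branch.get(branch, ()):
                ev = _sample_event(sub, branch, kind, params)
                if ev is None:
                    raise InputError(
                        f"forced {kind} on branch {branch!r} not applicable")
                sub.apply(ev)
                events.append(ev)
            sample_background(sub, branch, child.length - half)
            if child.is_leaf:
                leaf_genomes[child.name] = sub.to_genome(child.name, prefix=True)
            else:
                descend(child, sub)

    descend(tree, root)
    orthology = {
        taxon: {gid.split(".", 1)[1]: gid for gid in g.gene_ids()}
        for taxon, g in leaf_genomes.items()
    }
    return SimTruth(tree, events, root.to_genome("root"), leaf_genomes,
                    seed, orthology)


# ---------------------------------------------------------------------------
# Emission of on-disk artifacts
# ---------------------------------------------------------------------------

def identity_hits(
    genome_a: Genome, genome_b: Genome, seed: int = 0
) -> SimilarityHits:
    """Similarity hits between two leaf genomes: every shared base gene gets
    a strong self-hit plus one weak decoy hit, so best-hit selection is
    exercised without sequence simulation."""
    rng = np.random.default_rng(seed)
    base_a = {g.split(".", 1)[1]: g for g in genome_a.gene_ids()}
    base_b = {g.split(".", 1)[1]: g for g in genome_b.gene_ids()}
    shared = sorted(set(base_a) & set(base_b))
    targets = [base_b[s] for s in shared]
    hits = SimilarityHits()
    for s in shared:
        hits.add(base_a[s], base_b[s], 500.0, 1e-100)
        decoy = targets[int(rng.integers(len(targets)))]
        if decoy != base_b[s]:
            hits.add(base_a[s], decoy, float(rng.uniform(50, 200)), 1e-5)
    return hits


def write_simulation(truth: SimTruth, outdir: str | Path, seed: int = 0) -> None:
    """Emit per-leaf .chrom files, pairwise hit tables in both directions,
    and a truth JSON (tree + event log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon, genome in truth.leaf_genomes.items():
        write_gene_map(genome, outdir / f"{taxon}.chrom")
    taxa = sorted(truth.leaf_genomes)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            sub = int(np.random.SeedSequence([seed, i, taxa.index(b)])
                      .generate_state(1)[0] % (2**31))
            write_hits(identity_hits(truth.leaf_genomes[a],
                                     truth.leaf_genomes[b], sub),
                       outdir / f"{a}__{b}.hits.tsv")
            write_hits(identity_hits(truth.leaf_genomes[b],
                                     truth.leaf_genomes[a], sub + 1),
                       outdir / f"{b}__{a}.hits.tsv")
    payload = {
        "seed": truth.seed,
        "tree": truth.tree.newick(),
        "events": [
            {"branch": e.branch, "kind": e.kind, "params": e.p}
            for e in truth.events
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
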