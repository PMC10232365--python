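"""One-to-one orthology: reciprocal best hits, n-way cliques, anchor joining.

The orthology model is deliberately conservative: a pairwise orthologue is a
reciprocal best hit (RBH) by bitscore, and an n-way orthogroup is a gene tuple
(one gene per species) in which *every* one of the C(n,2) pairs is an RBH — a
clique, not a connected component.  Queries whose best bitscore is tied
between targets are dropped entirely rather than assigned arbitrarily.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InputError, ParseError
from .genome import SimilarityHits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthoGroup:
    """An n-way orthogroup: exactly one gene per species.

    Equality and hashing consider only the membership, so identical groups
    from different runs compare equal regardless of provenance.
    """

    items: tuple[tuple[str, str], ...]  # sorted (species_id, gene_id) pairs
    provenance: frozenset[str] = field(default=frozenset(), compare=False)
    conflict_flag: bool = field(default=False, compare=False)

    @classmethod
    def from_members(
        cls,
        members: Mapping[str, str],
        provenance: Iterable[str] = (),
        conflict_flag: bool = False,
    ) -> "OrthoGroup":
        return cls(tuple(sorted(members.items())), frozenset(provenance), conflict_flag)

    @property
    def members(self) -> dict[str, str]:
        return dict(self.items)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.items)

    def gene(self, species_id: str) -> str:
        for s, g in self.items:
            if s == species_id:
                return g
        raise KeyError(species_id)

    def __len__(self) -> int:
        return len(self.items)


class PairOrthologyMap:
    """A one-to-one set of orthologous gene pairs between two species."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self.a_to_b: dict[str, str] = {}
        self.b_to_a: dict[str, str] = {}
        for a, b in pairs:
            if a in self.a_to_b or b in self.b_to_a:
                raise InputError(f"pair ({a}, {b}) violates one-to-one constraint")
            self.a_to_b[a] = b
            self.b_to_a[b] = a

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.a_to_b.items())

    def transpose(self) -> "PairOrthologyMap":
        return PairOrthologyMap((b, a) for a, b in self.a_to_b.items())

    def __len__(self) -> int:
        return len(self.a_to_b)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.a_to_b.get(pair[0]) == pair[1]


def _unique_best(hits: SimilarityHits) -> dict[str, str]:
    """query -> its unique maximum-bitscore target; tied queries dropped."""
    best: dict[str, str] = {}
    for query, targets in hits.by_query().items():
        top = max(targets.values())
        winners = [t for t, s in targets.items() if s == top]
        if len(winners) == 1:
            best[query] = winners[0]
    return best


def reciprocal_best_hits(
    hits_ab: SimilarityHits, hits_ba: SimilarityHits
) -> PairOrthologyMap:
    """Pairs (a, b) where b is a's unique best target and vice versa.

    Raises :class:`InputError` if the two hit sets appear to share a query
    namespace (i.e. are not A->B and B->A searches).
    """
    overlap = hits_ab.queries() & hits_ba.queries()
    if overlap:
        raise InputError(
            f"hit sets share {len(overlap)} query ids; expected disjoint "
            "A->B and B->A searches"
        )
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return PairOrthologyMap(sorted(pairs))


def nway_groups(
    pair_maps: Mapping[tuple[str, str], PairOrthologyMap],
    species: Sequence[str],
) -> set[OrthoGroup]:
    """n-way orthogroups: gene tuples forming an RBH clique across all pairs.

    ``pair_maps`` must contain every unordered species pair, keyed by the
    ordered tuple matching the map's (a, b) orientation.
    """
    species = list(species)
    lookup: dict[tuple[str, str], PairOrthologyMap] = {}
    for (sa, sb) in itertools.combinations(species, 2):
        if (sa, sb) in pair_maps:
            lookup[(sa, sb)] = pair_maps[(sa, sb)]
        elif (sb, sa) in pair_maps:
            lookup[(sa, sb)] = pair_maps[(sb, sa)].transpose()
        else:
            raise InputError(f"missing pair map for species pair ({sa}, {sb})")

    first = species[0]
    groups: set[OrthoGroup] = set()
    # candidate tuples are determined by the first species' pairings
    for a_gene in sorted(lookup[(first, species[1])].a_to_b):
        members = {first: a_gene}
        ok = True
        for other in species[1:]:
            partner = lookup[(first, other)].a_to_b.get(a_gene)
            if partner is None:
                ok = False
                break
            members[other] = partner
        if not ok:
            continue
        # clique check over the remaining pairs
        for sa, sb in itertools.combinations(species[1:], 2):
            key = (sa, sb) if (sa, sb) in lookup else (sb, sa)
            if (members[key[0]], members[key[1]]) not in lookup[key]:
                ok = False
                break
        if ok:
            groups.add(OrthoGroup.from_members(members, provenance=("nway",)))
    return groups


def merge_groups_by_anchor(
    runs: Sequence[set[OrthoGroup]],
    anchor_species: Sequence[str],
    run_labels: Sequence[str] | None = None,
) -> set[OrthoGroup]:
    """Join orthogroups from separate runs whose anchor-species gene tuples
    are identical.

    Each run pairs a different outgroup species against a shared anchor trio;
    groups are merged when their genes in the anchor species coincide exactly,
    yielding combined groups that carry >= 1 non-anchor member.  Conflicting
    non-anchor assignments (same species, different gene) keep the first-seen
    gene and set ``conflict_flag``.
    """
    anchors = list(anchor_species)
    if run_labels is None:
        run_labels = [f"run{i}" for i in range(len(runs))]
    merged: dict[tuple[str, ...], dict] = {}
    for run, label in zip(runs, run_labels):
        for group in run:
            members = group.members
            missing = [s for s in anchors if s not in members]
            if missing:
                raise InputError(
                    f"group {group.items} missing anchor species {missing}"
                )
            key = tuple(members[s] for s in anchors)
            slot = merged.setdefault(
                key, {"members": {}, "provenance": set(), "conflict": False}
            )
            for sp, gene in members.items():
                if sp in slot["members"] and slot["members"][sp] != gene:
                    slot["conflict"] = True
                    logger.warning(
                        "anchor tuple %s: conflicting %s gene (%s vs %s)",
                        key, sp, slot["members"][sp], gene,
                    )
                else:
                    slot["members"].setdefault(sp, gene)
            slot["provenance"].update(group.provenance or {label})
            slot["provenance"].add(label)
    out: set[OrthoGroup] = set()
    for slot in merged.values():
        non_anchor = set(slot["members"]) - set(anchors)
        if not non_anchor:
            continue
        out.add(
            OrthoGroup.from_members(
                slot["members"], slot["provenance"], slot["conflict"]
            )
        )
    return out


def read_orthogroup_tsv(path: str | Path, species: Sequence[str]) -> set[OrthoGroup]:
    """Read a precomputed orthogroup table (one row per group, one column per
    species, comma-separated gene lists); keep only single-copy rows.

    Multi-copy or empty cells drop the row; the number of dropped rows is
    logged.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [s for s in species if s not in header]
        if missing:
            raise InputError(f"unknown species column(s) {missing} in {path}")
        idx = {s: header.index(s) for s in species}
        groups: set[OrthoGroup] = set()
        dropped = 0
        for lineno, raw in enumerate(fh, start=2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise ParseError("short row", path=str(path), line=lineno)
            members = {}
            ok = True
            for sp in species:
                genes = [g for g in fields[idx[sp]].replace(" ", "").split(",") if g]
                if len(genes) != 1:
                    ok = False
                    break
                members[sp] = genes[0]
            if ok:
                groups.add(OrthoGroup.from_members(members, provenance=("tsv",)))
            else:
                dropped += 1
    if dropped:
        logger.info("%s: dropped %d non-single-copy rows", path, dropped)
    return groups
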