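"""Conserved gene linkage groups and their permutation false-discovery rate.

Orthogroups are partitioned by the tuple of chromosomes their genes occupy
across the n input species; a group of size k co-resident in every species is
a candidate ancestral linkage group (ALG) occurrence.  Significance is a
permutation FDR: the genome coordinates of the in-scope species are shuffled
(gene identities permuted over each genome's fixed chromosome skeleton, so
per-chromosome gene counts are preserved exactly) and alpha(k) is the
frequency of permutations producing any co-resident set of size >= k, with a
+1 pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .genome import Genome
from .orthology import OrthoGroup

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenyGroup:
    """A set of orthogroups sharing one chromosome per species."""

    label: str
    chrom_tuple: tuple[tuple[str, str], ...]  # sorted (species, chromosome)
    members: frozenset[OrthoGroup]
    size_k: int
    alpha: float | None = None

    @property
    def chromosomes(self) -> dict[str, str]:
        return dict(self.chrom_tuple)

    def member_genes(self, species_id: str) -> set[str]:
        return {og.gene(species_id) for og in self.members}


@dataclass
class AlphaTable:
    """Tail FDR estimates: alpha(k) = P(any co-resident set of size >= k)."""

    counts: dict[int, int]  # k -> number of permutations with max size >= k
    n_perm: int
    seed: int
    scheme: str = "any-occurrence"
    expected_counts: dict[int, float] = field(default_factory=dict)

    def alpha(self, k: int) -> float:
        if self.scheme == "expected-count":
            # mean number of size->=k groups per permutation, floored by the
            # pseudocount so alpha stays in (0, 1]
            val = (1.0 + self.expected_counts.get(k, 0.0) * self.n_perm) / (
                1.0 + self.n_perm
            )
            return min(1.0, val)
        return (1 + self.counts.get(k, 0)) / (1 + self.n_perm)

    def as_dict(self, k_max: int) -> dict[int, float]:
        return {k: self.alpha(k) for k in range(1, k_max + 1)}


def chromosome_tuple(
    orthogroup: OrthoGroup, genomes: Mapping[str, Genome]
) -> tuple[tuple[str, str], ...]:
    return tuple(
        sorted((sp, genomes[sp].chromosome_of(gene)) for sp, gene in orthogroup.items
               if sp in genomes)
    )


def identify_groups(
    orthogroups: set[OrthoGroup],
    genomes: Mapping[str, Genome],
    labels: Mapping[tuple[tuple[str, str], ...], str] | None = None,
) -> set[SyntenyGroup]:
    """Partition orthogroups by the chromosomes on which their genes occur.

    Output groups are disjoint, cover the input, and depend only on
    chromosome membership (never on gene order).  Labels default to
    ``SG<i>`` in decreasing size order; a mapping from chromosome tuple to a
    published ALG name (e.g. ``A1a_x``) may be supplied instead.
    """
    by_tuple: dict[tuple, set[OrthoGroup]] = {}
    for og in orthogroups:
        by_tuple.setdefault(chromosome_tuple(og, genomes), set()).add(og)
    ordered = sorted(by_tuple.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out: set[SyntenyGroup] = set()
    for i, (tup, members) in enumerate(ordered, start=1):
        label = (labels or {}).get(tup, f"SG{i:04d}")
        out.add(SyntenyGroup(label, tup, frozenset(members), len(members)))
    return out


def _species_arrays(
    orthogroups: Sequence[OrthoGroup], genomes: Mapping[str, Genome]
):
    """Precompute, per species: the chromosome-code skeleton (one code per
    gene position) and each orthogroup member's index in the gene list."""
    arrays = []
    for sp, genome in genomes.items():
        gene_ids = genome.gene_ids()
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        chrom_codes = {c: i for i, c in enumerate(genome.chromosomes)}
        skeleton = np.fromiter(
            (chrom_codes[g.chromosome] for g in genome.genes()),
            dtype=np.int64,
            count=len(gene_ids),
        )
        member_idx = np.fromiter(
            (gene_index[og.gene(sp)] for og in orthogroups),
            dtype=np.int64,
            count=len(orthogroups),
        )
        arrays.append((sp, skeleton, member_idx, len(chrom_codes)))
    return arrays


def permutation_alpha(
    orthogroups: set[OrthoGroup],
    genomes: Mapping[str, Genome],
    n_perm: int,
    seed: int,
    shuffle_scope: str = "all_species",
    scheme: str = "any-occurrence",
) -> AlphaTable:
    """Estimate the FDR of finding a co-resident orthologue set of size k.

    ``shuffle_scope`` is ``all_species`` or ``one_species:<id>``; out-of-scope
    genomes keep their true gene placement.  Permutation streams are drawn
    from a single seeded generator, so results are reproducible given
    (seed, n_perm).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if scheme not in ("any-occurrence", "expected-count"):
        raise InputError(f"unknown scheme {scheme!r}")
    ogs = sorted(orthogroups, key=lambda g: g.items)
    if shuffle_scope == "all_species":
        in_scope = set(genomes)
    elif shuffle_scope.startswith("one_species:"):
        sp = shuffle_scope.split(":", 1)[1]
        if sp not in genomes:
            raise InputError(f"unknown species {sp!r} in shuffle_scope")
        in_scope = {sp}
    else:
        raise InputError(f"bad shuffle_scope {shuffle_scope!r}")

    arrays = _species_arrays(ogs, genomes)
    n_og = len(ogs)
    rng = np.random.default_rng(seed)

    # fixed chromosome codes for out-of-scope species
    base_codes = []
    for sp, skeleton, member_idx, n_chrom in arrays:
        base_codes.append(skeleton[member_idx])

    tail_counts: dict[int, int] = {}
    sum_counts: dict[int, float] = {}
    for _ in range(n_perm):
        key = np.zeros(n_og, dtype=np.int64)
        for j, (sp, skeleton, member_idx, n_chrom) in enumerate(arrays):
            if sp in in_scope:
                perm = rng.permutation(skeleton.shape[0])
                codes = skeleton[perm[member_idx]]
            else:
                codes = base_codes[j]
            key = key * n_chrom + codes
        _, counts = np.unique(key, return_counts=True)
        max_size = int(counts.max()) if counts.size else 0
        for k in range(1, max_size + 1):
            tail_counts[k] = tail_counts.get(k, 0) + 1
        if scheme == "expected-count":
            sizes, freq = np.unique(counts, return_counts=True)
            for k in range(1, max_size + 1):
                sum_counts[k] = sum_counts.get(k, 0.0) + float(
                    freq[sizes >= k].sum()
                )
    expected = {k: v / n_perm for k, v in sum_counts.items()}
    logger.info(
        "permutation_alpha: n_perm=%d seed=%d scope=%s scheme=%s",
        n_perm, seed, shuffle_scope, scheme,
    )
    return AlphaTable(tail_counts, n_perm, seed, scheme, expected)


def significant_groups(
    groups: set[SyntenyGroup],
    alphas: AlphaTable,
    threshold: float = 0.05,
) -> set[SyntenyGroup]:
    """Annotate groups with alpha(size_k) and keep those at or below the
    threshold."""
    out = set()
    for g in groups:
        a = alphas.alpha(g.size_k)
        if a <= threshold:
            out.add(SyntenyGroup(g.label, g.chrom_tuple, g.members, g.size_k, a))
    return out
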