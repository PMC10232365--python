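"""Syntenic support for ctenophore-sister vs sponge-sister, with a
genome-shuffling null.

A character supports ctenophore-sister when the outgroup and the ctenophore
both retain the separate (0) state while the sponge and the
cnidarian/bilaterian representative are both fused (state >= 1): the fusion
is then a synapomorphy of sponge + cnidarian/bilaterian excluding
ctenophores.  Sponge-sister support is the mirror pattern.  The null
distribution is obtained by shuffling one species' gene -> position
assignment over its fixed chromosome skeleton and re-encoding the characters
each time; the one-sided FDR uses a +1 pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .characters import CharacterMatrix, build_character_matrix
from .errors import InputError
from .genome import Genome

logger = logging.getLogger(__name__)

ROLES = ("outgroup", "ctenophore", "sponge", "cnibil")


@dataclass(frozen=True)
class SupportCounts:
    n_groups_cteno: int
    n_genes_cteno: int
    n_groups_sponge: int
    n_genes_sponge: int


@dataclass
class ShuffleTestResult:
    observed: SupportCounts
    null_hist_cteno: dict[int, int]
    null_hist_sponge: dict[int, int]
    alpha_cteno: float
    alpha_sponge: float
    n_perm: int
    shuffled_species: str
    seed: int


def _pair_gene_count(
    pair: tuple[str, str, Mapping[str, set[str]], Mapping[str, set[str]]]
) -> int:
    _, _, mem_x, mem_y = pair
    sizes = [len(mem_x.get(t, ())) + len(mem_y.get(t, ()))
             for t in set(mem_x) | set(mem_y)]
    return max(sizes) if sizes else 0


def count_hypothesis_support(
    characters: CharacterMatrix,
    roles: Mapping[str, str],
    pair_genes: Mapping[tuple[str, str], int] | None = None,
) -> SupportCounts:
    """Count characters (and their genes) matching either hypothesis pattern.

    ``roles`` maps each taxon to one of outgroup/ctenophore/sponge/cnibil;
    every role must be present exactly once.  ``pair_genes`` optionally maps
    a character's pair label to its gene count; otherwise gene counts are
    taken from the character's mixing support (a + b on the fused taxon).
    """
    by_role = {}
    for taxon, role in roles.items():
        if role not in ROLES:
            raise InputError(f"unknown role {role!r}")
        if role in by_role:
            raise InputError(f"duplicate role {role!r}")
        by_role[role] = taxon
    missing = [r for r in ROLES if r not in by_role]
    if missing:
        raise InputError(f"missing role(s) {missing}")

    def genes_of(ch) -> int:
        if pair_genes is not None:
            return pair_genes.get(ch.pair_label, 0)
        sizes = [res.a + res.b for _, res in ch.support]
        return max(sizes) if sizes else 0

    fused = lambda s: s in ("1", "2")
    gc = gs = nc = ns = 0
    for ch in characters.characters:
        s = {role: ch.state(taxon) for role, taxon in by_role.items()}
        if s["outgroup"] == "0" and s["ctenophore"] == "0" and \
                fused(s["sponge"]) and fused(s["cnibil"]):
            nc += 1
            gc += genes_of(ch)
        if s["outgroup"] == "0" and s["sponge"] == "0" and \
                fused(s["ctenophore"]) and fused(s["cnibil"]):
            ns += 1
            gs += genes_of(ch)
    return SupportCounts(nc, gc, ns, gs)


class _ShuffledEncoder:
    """Re-encodes one species' fusion states under gene->position shuffles.

    The chromosome skeleton (per-chromosome gene counts, concatenated in a
    fixed order) is immutable; a permutation assigns each gene a new global
    position, which determines both its chromosome and its rank.
    """

    def __init__(self, genome: Genome,
                 pairs: Sequence[tuple[str, str, Mapping, Mapping]]):
        self.genome = genome
        gene_ids = genome.gene_ids()
        index = {g: i for i, g in enumerate(gene_ids)}
        self.n = len(gene_ids)
        chrom_code = {c: i for i, c in enumerate(genome.chromosomes)}
        self.n_chrom = len(chrom_code)
        self.skeleton = np.fromiter(
            (chrom_code[g.chromosome] for g in genome.genes()),
            dtype=np.int64, count=self.n,
        )
        sp = genome.species_id
        self.pair_idx = []
        for label_x, label_y, mem_x, mem_y in pairs:
            ix = np.array([index[g] for g in sorted(mem_x.get(sp, ()))
                           if g in index], dtype=np.int64)
            iy = np.array([index[g] for g in sorted(mem_y.get(sp, ()))
                           if g in index], dtype=np.int64)
            self.pair_idx.append((ix, iy))
        self._cdf_cache: dict[tuple[int, int], np.ndarray] = {}

    def _runs_cdf(self, a: int, b: int) -> np.ndarray:
        key = (a, b)
        if key not in self._cdf_cache:
            from .mixing import runs_null_exact

            self._cdf_cache[key] = np.cumsum(runs_null_exact(a, b))
        return self._cdf_cache[key]

    def states(self, perm: np.ndarray, localization_fraction: float = 0.8,
               threshold: float = 0.05) -> list[str]:
        """Fusion state of every pair given a gene->position permutation."""
        out = []
        for ix, iy in self.pair_idx:
            if ix.size == 0 or iy.size == 0:
                out.append("?")
                continue
            px, py = perm[ix], perm[iy]
            cx_codes, cy_codes = self.skeleton[px], self.skeleton[py]
            bx = np.bincount(cx_codes, minlength=self.n_chrom)
            by = np.bincount(cy_codes, minlength=self.n_chrom)
            cx, cy = int(bx.argmax()), int(by.argmax())
            if bx[cx] / ix.size < localization_fraction or \
                    by[cy] / iy.size < localization_fraction:
                out.append("?")
                continue
            if cx != cy:
                out.append("0")
                continue
            pos_x = px[cx_codes == cx]
            pos_y = py[cy_codes == cy]
            a, b = pos_x.size, pos_y.size
            pos = np.concatenate([pos_x, pos_y])
            lab = np.concatenate([np.zeros(a, np.int8), np.ones(b, np.int8)])
            order = np.argsort(pos)
            lab = lab[order]
            t_obs = int(np.sum(lab[1:] != lab[:-1]))
            alpha = float(self._runs_cdf(a, b)[t_obs])
            out.append("1" if alpha < threshold else "2")
        return out


def shuffle_hypothesis_test(
    genomes: Mapping[str, Genome],
    pairs: Sequence[tuple[str, str, Mapping[str, set[str]], Mapping[str, set[str]]]],
    roles: Mapping[str, str],
    shuffled_species: str,
    n_perm: int,
    seed: int,
    localization_fraction: float = 0.8,
    threshold: float = 0.05,
) -> ShuffleTestResult:
    """Genome-shuffling null for hypothesis support counts.

    Only ``shuffled_species``' states are re-encoded per permutation; the
    other taxa keep their observed states.  Aggregation is streaming, so
    memory is O(1) in ``n_perm``.
    """
    if shuffled_species not in genomes:
        raise InputError(f"shuffled species {shuffled_species!r} not in genomes")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    matrix = build_character_matrix(genomes, pairs, localization_fraction, threshold)
    pair_genes = {
        (p[0], p[1]): _pair_gene_count(p) for p in pairs
    }
    observed = count_hypothesis_support(matrix, roles, pair_genes)

    genome = genomes[shuffled_species]
    if genome.karyotype_n == 1:
        logger.warning(
            "%s has a single chromosome: shuffle null is degenerate",
            shuffled_species,
        )
    ordered_pairs = sorted(pairs, key=lambda p: (p[0], p[1]))
    encoder = _ShuffledEncoder(genome, ordered_pairs)
    # fixed states of the other taxa, in encoder pair order
    fixed = {
        taxon: [matrix.characters[j].state(taxon) for j in range(len(matrix))]
        for taxon in matrix.taxa if taxon != shuffled_species
    }
    role_of = dict(roles)
    by_role = {r: t for t, r in roles.items()}
    gene_counts = [ _pair_gene_count(p) for p in ordered_pairs ]

    rng = np.random.default_rng(seed)
    hist_c: dict[int, int] = {}
    hist_s: dict[int, int] = {}
    n_ge_c = n_ge_s = 0
    fused = ("1", "2")
    # per-pair fixed states for the three unshuffled roles
    fixed_by_role = {}
    for role, taxon in by_role.items():
        if taxon != shuffled_species:
            fixed_by_role[role] = fixed[taxon]
    shuffled_role = role_of[shuffled_species]
    for _ in range(n_perm):
        perm = rng.permutation(encoder.n)
        new_states = encoder.states(perm, localization_fraction, threshold)
        nc = ns = 0
        for j in range(len(ordered_pairs)):
            s = {r: v[j] for r, v in fixed_by_role.items()}
            s[shuffled_role] = new_states[j]
            if s["outgroup"] == "0" and s["ctenophore"] == "0" and \
                    s["sponge"] in fused and s["cnibil"] in fused:
                nc += 1
            if s["outgroup"] == "0" and s["sponge"] == "0" and \
                    s["ctenophore"] in fused and s["cnibil"] in fused:
                ns += 1
        hist_c[nc] = hist_c.get(nc, 0) + 1
        hist_s[ns] = hist_s.get(ns, 0) + 1
        if nc >= observed.n_groups_cteno:
            n_ge_c += 1
        if ns >= observed.n_groups_sponge:
            n_ge_s += 1
    return ShuffleTestResult(
        observed,
        dict(sorted(hist_c.items())),
        dict(sorted(hist_s.items())),
        (1 + n_ge_c) / (1 + n_perm),
        (1 + n_ge_s) / (1 + n_perm),
        n_perm,
        shuffled_species,
        seed,
    )
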