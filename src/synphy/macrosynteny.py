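"""Pairwise chromosome homology by one-sided Fisher's exact tests.

For two species linked by a one-to-one orthology map, every orthologous pair
falls in one cell of a 2x2 table for each (chrom_a, chrom_b) combination:
on both chromosomes / on chrom_a only / on chrom_b only / on neither.  The
one-sided (enrichment) p-value is the upper hypergeometric tail, and the
family of tests actually computed (combinations with at least one shared
pair) is Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .genome import Genome
from .orthology import OrthoGroup, PairOrthologyMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChromAssociation:
    chrom_a: str
    chrom_b: str
    n_shared: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    p_raw: float
    p_adjusted: float
    significant: bool


def fisher_one_sided(
    n_shared: int, n_a_only: int, n_b_only: int, n_neither: int
) -> float:
    """Upper-tail (enrichment) p-value for a 2x2 table.

    P(X >= n_shared) where X ~ Hypergeom(N, K=row margin, n=column margin).
    """
    total = n_shared + n_a_only + n_b_only + n_neither
    row = n_shared + n_a_only
    col = n_shared + n_b_only
    return float(hypergeom.sf(n_shared - 1, total, row, col))


def chromosome_association(
    genome_a: Genome,
    genome_b: Genome,
    pairs: PairOrthologyMap,
    alpha: float = 0.05,
) -> list[ChromAssociation]:
    """Test every (chrom_a, chrom_b) combination with >= 1 shared orthologue.

    Bonferroni family size m = number of tests performed; significant iff
    p_raw * m <= alpha.
    """
    placed = [
        (genome_a.chromosome_of(a), genome_b.chromosome_of(b))
        for a, b in sorted(pairs.pairs)
    ]
    total = len(placed)
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    shared: dict[tuple[str, str], int] = {}
    for ca, cb in placed:
        count_a[ca] = count_a.get(ca, 0) + 1
        count_b[cb] = count_b.get(cb, 0) + 1
        shared[(ca, cb)] = shared.get((ca, cb), 0) + 1

    m = len(shared)
    logger.info(
        "macrosynteny %s vs %s: %d orthologous pairs, %d tests (Bonferroni m)",
        genome_a.species_id, genome_b.species_id, total, m,
    )
    out = []
    for (ca, cb) in sorted(shared):
        k = shared[(ca, cb)]
        a_only = count_a[ca] - k
        b_only = count_b[cb] - k
        neither = total - k - a_only - b_only
        p = fisher_one_sided(k, a_only, b_only, neither)
        p_adj = min(1.0, p * m)
        out.append(
            ChromAssociation(ca, cb, k, a_only, b_only, neither, p, p_adj, p_adj <= alpha)
        )
    return out


def association_table(associations: list[ChromAssociation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in associations])


def ribbon_table(
    genomes: list[Genome],
    orthogroups: set[OrthoGroup],
    group_labels: dict[OrthoGroup, str] | None = None,
) -> pd.DataFrame:
    """Plot-ready ribbon data for adjacent species pairs.

    One row per orthogroup per adjacent genome pair, with rank-normalized
    positions ((rank + 0.5) / m, midpoint convention) in [0, 1].  Rows where
    the orthogroup lacks a member in either species of the pair are omitted.
    Restricting to a single pair gives Oxford dot-plot data.
    """
    if len(genomes) < 2:
        raise ValueError("ribbon_table needs >= 2 genomes")
    rows = []
    for og in sorted(orthogroups, key=lambda g: g.items):
        members = og.members
        label = (group_labels or {}).get(og, "")
        for ga, gb in zip(genomes, genomes[1:]):
            if ga.species_id not in members or gb.species_id not in members:
                continue
            la = ga.locate(members[ga.species_id])
            lb = gb.locate(members[gb.species_id])
            ma = len(ga.chromosomes[la.chromosome])
            mb = len(gb.chromosomes[lb.chromosome])
            rows.append(
                {
                    "species_a": ga.species_id,
                    "species_b": gb.species_id,
                    "gene_a": la.gene_id,
                    "gene_b": lb.gene_id,
                    "chrom_a": la.chromosome,
                    "chrom_b": lb.chromosome,
                    "pos_a": (la.rank + 0.5) / ma,
                    "pos_b": (lb.rank + 0.5) / mb,
                    "label": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a", "species_b", "gene_a", "gene_b",
            "chrom_a", "chrom_b", "pos_a", "pos_b", "label",
        ],
    )
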