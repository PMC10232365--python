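"""The fusion-mixing statistic: transitions between two gene sets along a
chromosome, with exact (runs-distribution) and permutation nulls.

After two ancestral linkage groups fuse onto one chromosome, subsequent
intrachromosomal rearrangement interleaves their genes.  The statistic counts
adjacent transitions between a gene of subgroup ``x`` and a gene of subgroup
``y`` in rank order (genes in neither subgroup are ignored, so only relative
order matters).  Under the null of uniform random interleaving of a x-genes
and b y-genes, the number of runs r (t = r - 1 transitions) follows the
classical Wald–Wolfowitz runs distribution; alpha = P(T <= t_obs) is the
lower tail, so a small alpha means the arrangement is significantly more
segregated than random — "unmixed".  The working convention alpha < 0.05 =>
unmixed is applied as the verdict threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .errors import InputError
from .genome import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixingResult:
    a: int
    b: int
    t_obs: int
    alpha: float
    verdict: str  # unmixed | mixed | indeterminate
    method: str  # exact | permutation


def transition_count(arrangement: Sequence[str]) -> int:
    """Number of adjacent positions with differing labels in a binary
    sequence."""
    if len(arrangement) == 0:
        raise InputError("arrangement must be nonempty")
    labels = set(arrangement)
    if not labels <= {"x", "y"}:
        raise InputError(f"non-binary labels {labels - {'x', 'y'}}")
    arr = np.asarray([0 if c == "x" else 1 for c in arrangement])
    return int(np.sum(arr[1:] != arr[:-1]))


def runs_null_exact(a: int, b: int) -> np.ndarray:
    """Exact pmf of the transition count T for random arrangements of a x's
    and b y's.

    Returns an array p where p[t] = P(T = t), t = 0..2*min(a,b).  The number
    of arrangements with r runs is the classical two-sample runs count:
    r = 2m:   2*C(a-1, m-1)*C(b-1, m-1)
    r = 2m+1: C(a-1, m-1)*C(b-1, m) + C(a-1, m)*C(b-1, m-1)
    and T = r - 1.
    """
    if a < 1 or b < 1:
        raise InputError("runs_null_exact requires a >= 1 and b >= 1")
    total = comb(a + b, a)
    t_max = 2 * min(a, b) - (1 if a == b else 0)
    pmf = np.zeros(t_max + 1)
    for r in range(2, a + b + 1):
        if r % 2 == 0:
            m = r // 2
            ways = 2 * comb(a - 1, m - 1) * comb(b - 1, m - 1)
        else:
            m = (r - 1) // 2
            ways = comb(a - 1, m - 1) * comb(b - 1, m) + comb(a - 1, m) * comb(
                b - 1, m - 1
            )
        if ways and r - 1 <= t_max:
            pmf[r - 1] = ways / total
    return pmf


def exact_alpha(a: int, b: int, t_obs: int) -> float:
    """Lower-tail P(T <= t_obs) under the exact runs null."""
    pmf = runs_null_exact(a, b)
    return float(pmf[: t_obs + 1].sum())


def permutation_alpha_estimate(
    a: int, b: int, t_obs: int, n_perm: int, seed: int
) -> float:
    """Monte-Carlo estimate of P(T <= t_obs) with a +1 pseudocount."""
    rng = np.random.default_rng(seed)
    base = np.concatenate([np.zeros(a, dtype=np.int8), np.ones(b, dtype=np.int8)])
    # one shuffle per row, transitions via sign changes
    mat = np.tile(base, (n_perm, 1))
    idx = np.argsort(rng.random((n_perm, a + b)), axis=1)
    shuffled = np.take_along_axis(mat, idx, axis=1)
    t = np.sum(shuffled[:, 1:] != shuffled[:, :-1], axis=1)
    return float((1 + np.sum(t <= t_obs)) / (1 + n_perm))


def mixing_alpha(
    genome: Genome,
    chromosome: str,
    set_x: set[str],
    set_y: set[str],
    method: str = "exact",
    n_perm: int = 10_000,
    seed: int = 0,
    threshold: float = 0.05,
    exact_limit: int = 2000,
) -> MixingResult:
    """Mixing verdict for two gene sets on one chromosome.

    The arrangement is the x/y labelling of the subgroup genes in rank order
    on ``chromosome``; genes of either set lying elsewhere are ignored with a
    warning.  ``method='exact'`` uses the closed-form runs null when
    a + b <= exact_limit, else falls back to permutation.
    """
    if set_x & set_y:
        raise InputError(f"set_x and set_y overlap: {sorted(set_x & set_y)[:5]}")
    loci = genome.chromosomes.get(chromosome, [])
    labelled = []
    on_chrom = {g.gene_id for g in loci}
    stray = (set_x | set_y) - on_chrom
    present_elsewhere = {g for g in stray if g in genome}
    if present_elsewhere:
        logger.warning(
            "%s:%s: %d subgroup genes located on other chromosomes; ignored",
            genome.species_id, chromosome, len(present_elsewhere),
        )
    for locus in loci:
        if locus.gene_id in set_x:
            labelled.append("x")
        elif locus.gene_id in set_y:
            labelled.append("y")
    a = labelled.count("x")
    b = labelled.count("y")
    if a == 0 or b == 0:
        return MixingResult(a, b, 0, 1.0, "indeterminate", method)
    t_obs = transition_count(labelled)
    if method == "exact" and a + b <= exact_limit:
        alpha = exact_alpha(a, b, t_obs)
        used = "exact"
    elif method in ("exact", "permutation"):
        alpha = permutation_alpha_estimate(a, b, t_obs, n_perm, seed)
        used = "permutation"
    else:
        raise InputError(f"unknown method {method!r}")
    verdict = "unmixed" if alpha < threshold else "mixed"
    return MixingResult(a, b, t_obs, alpha, verdict, used)
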