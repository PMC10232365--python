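"""Fusion-state characters and quartet classification.

Each candidate character is a pair of ancestral linkage subgroups (labelled
``_x`` and ``_y``).  Per taxon the state is:

* ``0`` — subgroups on separate chromosomes (ancestral, separate),
* ``1`` — co-resident on one chromosome but segregated (fused, unmixed),
* ``2`` — co-resident and interleaved (fused and mixed; irreversible),
* ``?`` — unknown (subgroup lost, split across chromosomes, or unplaced).

The quartet logic polarizes a character with an outgroup O and three ingroups
A, B, C: a fusion shared by exactly two ingroups while the third matches the
unfused outgroup is a synapomorphy uniting those two.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError
from .genome import Genome
from .mixing import MixingResult, mixing_alpha

logger = logging.getLogger(__name__)

STATES = ("0", "1", "2", "?")


@dataclass(frozen=True)
class FusionCharacter:
    pair_label: tuple[str, str]
    states: tuple[tuple[str, str], ...]  # (taxon, state), in taxa order
    support: tuple[tuple[str, MixingResult], ...] = field(default=(), compare=False)

    @property
    def state_map(self) -> dict[str, str]:
        return dict(self.states)

    def state(self, taxon: str) -> str:
        return self.state_map[taxon]


@dataclass
class CharacterMatrix:
    taxa: list[str]
    characters: list[FusionCharacter]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxa in matrix")
        for ch in self.characters:
            if set(ch.state_map) != set(self.taxa):
                raise InputError(
                    f"character {ch.pair_label} states do not match taxa"
                )

    def __len__(self) -> int:
        return len(self.characters)

    def state(self, taxon: str, j: int) -> str:
        return self.characters[j].state(taxon)

    def row(self, taxon: str) -> str:
        return "".join(ch.state(taxon) for ch in self.characters)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "_".join(ch.pair_label): [ch.state(t) for t in self.taxa]
            for ch in self.characters
        }
        return pd.DataFrame(data, index=self.taxa)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="taxon")

    def write_nexus(
        self,
        path: str | Path,
        step_matrix: Sequence[Sequence[float]] | None = None,
        mrbayes_block: bool = False,
    ) -> None:
        """NEXUS export with symbols 012, missing '?', and an ASSUMPTIONS
        block carrying a user step matrix for external parsimony/Bayesian
        programs."""
        lines = ["#NEXUS", "", "BEGIN DATA;"]
        lines.append(
            f"    DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(self.characters)};"
        )
        lines.append('    FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=?;')
        lines.append("    MATRIX")
        width = max(len(t) for t in self.taxa) + 2
        for t in self.taxa:
            lines.append(f"        {t:<{width}}{self.row(t)}")
        lines.append("    ;")
        lines.append("END;")
        if step_matrix is not None:
            lines.append("")
            lines.append("BEGIN ASSUMPTIONS;")
            lines.append("    USERTYPE fusionsteps (STEPMATRIX) = 3")
            lines.append("        0 1 2")
            for i, row in enumerate(step_matrix):
                cells = []
                for j, c in enumerate(row):
                    if i == j:
                        cells.append(".")
                    elif c == float("inf"):
                        cells.append("i")
                    else:
                        cells.append(f"{c:g}")
                lines.append("        " + " ".join(cells))
            lines.append("    ;")
            lines.append("    TYPESET * default = fusionsteps: ALL;")
            lines.append("END;")
        if mrbayes_block:
            lines.append("")
            lines.append("BEGIN MRBAYES;")
            lines.append("    lset coding=variable rates=equal;")
            lines.append("    mcmc ngen=100000 samplefreq=10 burninfrac=0.25;")
            lines.append("END;")
        Path(path).write_text("\n".join(lines) + "\n")


def encode_fusion_state(
    genome: Genome,
    members_x: set[str],
    members_y: set[str],
    localization_fraction: float = 0.8,
    threshold: float = 0.05,
) -> tuple[str, MixingResult | None]:
    """Fusion state of a subgroup pair in one taxon.

    Each subgroup is assigned its majority chromosome; if either majority
    fraction falls below ``localization_fraction`` the state is '?'.  When
    the majority chromosomes differ the state is 0; when they coincide the
    mixing test decides 1 (unmixed) vs 2 (mixed).
    """
    if members_x & members_y:
        raise InputError("subgroups overlap")

    def majority(genes: set[str]) -> tuple[str | None, float]:
        located = [genome.chromosome_of(g) for g in sorted(genes) if g in genome]
        if not located:
            return None, 0.0
        counts = Counter(located)
        # deterministic tie-break: larger count, then chromosome name
        chrom, top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        return chrom, top / len(located)

    if not members_x or not members_y:
        logger.warning("%s: empty subgroup -> '?'", genome.species_id)
        return "?", None
    cx, fx = majority(members_x)
    cy, fy = majority(members_y)
    if cx is None or cy is None:
        logger.warning("%s: subgroup unlocatable -> '?'", genome.species_id)
        return "?", None
    if fx < localization_fraction or fy < localization_fraction:
        return "?", None
    if cx != cy:
        return "0", None
    result = mixing_alpha(
        genome, cx, members_x, members_y, method="exact", threshold=threshold
    )
    if result.verdict == "indeterminate":
        return "?", result
    return ("1" if result.verdict == "unmixed" else "2"), result


QUARTET_PATTERNS = (
    "ancestral",
    "outgroup_fusion_or_fission",
    "single_lineage_fusion",
    "shared_fusion",
    "shared_fusion_with_mixing",
    "conflicting",
    "uninformative",
)


def classify_quartet(
    state_o: str, state_a: str, state_b: str, state_c: str
) -> tuple[str, frozenset[str] | None]:
    """Classify a quartet state pattern; returns (pattern, implied clade).

    The implied clade names the ingroup positions ('A', 'B', 'C') united by a
    shared fusion; it is None for all other patterns.  A shared fusion counts
    as *with mixing* only when both fused taxa are in state 2 — mixing in a
    single lineage is lineage-specific and the character then only evidences
    the (reversible) shared fusion.
    """
    states = (state_o, state_a, state_b, state_c)
    for s in states:
        if s not in STATES:
            raise InputError(f"invalid state {s!r}")
    if "?" in states:
        return "uninformative", None
    o = state_o
    ingroup = {"A": state_a, "B": state_b, "C": state_c}
    fused = {k for k, v in ingroup.items() if v != "0"}
    if len(set(states)) == 1:
        return "ancestral", None
    if o != "0":
        if not fused:
            return "outgroup_fusion_or_fission", None
        if len(fused) == 3:
            return "ancestral", None  # fusion ancestral to all four
        return "conflicting", None
    # outgroup unfused
    if len(fused) == 0:
        return "ancestral", None
    if len(fused) == 1:
        return "single_lineage_fusion", None
    if len(fused) == 2:
        pair = frozenset(fused)
        if all(ingroup[k] == "2" for k in fused):
            return "shared_fusion_with_mixing", pair
        return "shared_fusion", pair
    # all three ingroups fused, outgroup not: a fusion on the ingroup stem,
    # uninformative for branching among A, B, C
    return "uninformative", None


def build_character_matrix(
    genomes: Mapping[str, Genome],
    pairs: Sequence[tuple[str, str, Mapping[str, set[str]], Mapping[str, set[str]]]],
    localization_fraction: float = 0.8,
    threshold: float = 0.05,
) -> CharacterMatrix:
    """Assemble a character matrix from subgroup pair definitions.

    ``pairs`` entries are (label_x, label_y, members_x, members_y) where the
    member mappings give the per-taxon gene sets of each subgroup.  Taxa
    without locatable members score '?'.  Characters are ordered by pair
    label.
    """
    taxa = list(genomes)
    seen: set[tuple[str, str]] = set()
    characters = []
    for label_x, label_y, mem_x, mem_y in sorted(pairs, key=lambda p: (p[0], p[1])):
        key = (label_x, label_y)
        if key in seen:
            raise InputError(f"duplicate pair label {key}")
        seen.add(key)
        states = []
        support = []
        for taxon in taxa:
            gx = set(mem_x.get(taxon, set()))
            gy = set(mem_y.get(taxon, set()))
            state, res = encode_fusion_state(
                genomes[taxon], gx, gy, localization_fraction, threshold
            )
            states.append((taxon, state))
            if res is not None:
                support.append((taxon, res))
        characters.append(FusionCharacter(key, tuple(states), tuple(support)))
    return CharacterMatrix(taxa, characters)
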