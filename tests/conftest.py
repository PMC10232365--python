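"""Shared fixtures: tiny genomes and the published fusion-character matrix."""

import pytest
from hypothesis import settings

from synphy.characters import CharacterMatrix, FusionCharacter
from synphy.genome import GeneLocus, Genome

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

TAXA = ["OUT", "CTE", "SPO", "CNI", "BIL"]


def make_genome(species_id: str, chrom_genes: dict[str, list[str]]) -> Genome:
    """Genome with genes laid out in list order (1 kb spacing)."""
    loci = []
    for chrom, genes in chrom_genes.items():
        for i, g in enumerate(genes):
            start = i * 1000 + 1
            loci.append(GeneLocus(g, chrom, start, start + 500, "+"))
    return Genome.from_loci(species_id, loci)


@pytest.fixture
def arrangement_genome():
    """One chromosome holding x1..x5 then y1..y5, plus a second chromosome."""
    return make_genome(
        "T",
        {
            "chr1": [f"x{i}" for i in range(1, 6)] + [f"y{i}" for i in range(1, 6)],
            "chr2": [f"z{i}" for i in range(1, 6)],
        },
    )


def reported_fusion_matrix() -> CharacterMatrix:
    """The seven-character fusion matrix: outgroup and ctenophore separate
    (0) throughout; the demosponge mixed (2) for four characters and fused
    but unmixed (1) for three; cnidarian and bilaterian mixed throughout."""
    spo = ["2", "2", "2", "2", "1", "1", "1"]
    chars = []
    for j in range(7):
        states = {"OUT": "0", "CTE": "0", "SPO": spo[j], "CNI": "2", "BIL": "2"}
        chars.append(
            FusionCharacter((f"f{j}", "pair"), tuple((t, states[t]) for t in TAXA))
        )
    return CharacterMatrix(list(TAXA), chars)


@pytest.fixture(scope="session")
def reported_matrix() -> CharacterMatrix:
    return reported_fusion_matrix()
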