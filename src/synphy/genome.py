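"""Genome data model and readers/writers for gene-coordinate and similarity-hit tables.

A :class:`Genome` is a species' gene complement partitioned into chromosomes,
each an ordered list of :class:`GeneLocus` records.  All downstream synteny
statistics operate on *ranks* (order along the chromosome), never on base-pair
coordinates, so the canonical in-memory form is the rank order; coordinates are
preserved only for round-tripping and plotting.

Two on-disk dialects are supported for gene maps:

* ``chrom`` — 5 whitespace/tab-separated columns:
  ``gene_id  scaffold  strand  start  stop`` with 1-based inclusive coordinates.
* ``bed`` — BED with >= 4 columns (``chrom start end name [score] [strand]``),
  0-based half-open, converted to 1-based inclusive on read.

Similarity hits use the conventional 12-column tabular dialect
(query, target, pident, length, mismatch, gapopen, qstart, qend, tstart,
tend, evalue, bitscore); multiple HSPs per (query, target) are collapsed to
the maximum bitscore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, ParseError

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a chromosome.

    ``rank`` is the 0-based order of the gene along its chromosome after
    sorting by (start, gene_id); ranks on a chromosome are 0..m-1 with no
    gaps or duplicates.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IntegrityError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in _STRANDS:
            raise IntegrityError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class Genome:
    """A species' chromosomes, each an ordered (by rank) list of loci."""

    def __init__(self, species_id: str, chromosomes: Mapping[str, list[GeneLocus]]):
        self.species_id = species_id
        self.chromosomes: dict[str, list[GeneLocus]] = {
            c: list(loci) for c, loci in chromosomes.items()
        }
        self._index: dict[str, GeneLocus] = {}
        for chrom, loci in self.chromosomes.items():
            for i, locus in enumerate(loci):
                if locus.gene_id in self._index:
                    raise IntegrityError(
                        f"duplicate gene_id {locus.gene_id!r} in {species_id}"
                    )
                if locus.chromosome != chrom or locus.rank != i:
                    raise IntegrityError(
                        f"gene {locus.gene_id}: inconsistent chromosome/rank"
                    )
                self._index[locus.gene_id] = locus

    @classmethod
    def from_loci(cls, species_id: str, loci: Iterable[GeneLocus]) -> "Genome":
        """Build a genome, sorting each chromosome by (start, gene_id) and
        assigning ranks.  The incoming ``rank`` fields are ignored."""
        by_chrom: dict[str, list[GeneLocus]] = {}
        for locus in loci:
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        chromosomes: dict[str, list[GeneLocus]] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
            chromosomes[chrom] = [
                GeneLocus(g.gene_id, g.chromosome, g.start, g.end, g.strand, i)
                for i, g in enumerate(ordered)
            ]
        return cls(species_id, chromosomes)

    # -- queries ---------------------------------------------------------

    @property
    def karyotype_n(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def locate(self, gene_id: str) -> GeneLocus:
        try:
            return self._index[gene_id]
        except KeyError:
            raise IntegrityError(
                f"gene {gene_id!r} absent from genome {self.species_id}"
            ) from None

    def chromosome_of(self, gene_id: str) -> str:
        return self.locate(gene_id).chromosome

    def genes(self) -> Iterator[GeneLocus]:
        for loci in self.chromosomes.values():
            yield from loci

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes()]

    def chromosome_sizes(self) -> dict[str, int]:
        return {c: len(loci) for c, loci in self.chromosomes.items()}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Genome({self.species_id!r}, n={self.karyotype_n}, "
            f"genes={self.n_genes})"
        )


def read_gene_map(path: str | Path, format: str = "chrom") -> Genome:
    """Read a gene coordinate table into a :class:`Genome`.

    The species id is taken from the file stem.  Rows sharing a start
    coordinate are ordered by gene_id (stable total order).
    """
    path = Path(path)
    if format not in ("chrom", "bed"):
        raise ValueError(f"unknown format {format!r}")
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if format == "chrom":
                    if len(fields) != 5:
                        raise ValueError(f"expected 5 fields, got {len(fields)}")
                    gene_id, chrom, strand, start_s, end_s = fields
                    start, end = int(start_s), int(end_s)
                else:  # BED, 0-based half-open
                    if len(fields) < 4:
                        raise ValueError(f"expected >=4 fields, got {len(fields)}")
                    chrom, start_s, end_s, gene_id = fields[:4]
                    strand = fields[5] if len(fields) >= 6 else "."
                    start, end = int(start_s) + 1, int(end_s)
                locus = GeneLocus(gene_id, chrom, start, end, strand)
            except (ValueError, IntegrityError) as exc:
                raise ParseError(str(exc), path=str(path), line=lineno) from exc
            if gene_id in seen:
                raise IntegrityError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                )
            seen.add(gene_id)
            loci.append(locus)
    return Genome.from_loci(path.stem, loci)


def write_gene_map(genome: Genome, path: str | Path, format: str = "chrom") -> None:
    """Write a genome back to disk in the given dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        for locus in genome.genes():
            if format == "chrom":
                fh.write(
                    f"{locus.gene_id}\t{locus.chromosome}\t{locus.strand}"
                    f"\t{locus.start}\t{locus.end}\n"
                )
            elif format == "bed":
                fh.write(
                    f"{locus.chromosome}\t{locus.start - 1}\t{locus.end}"
                    f"\t{locus.gene_id}\t0\t{locus.strand}\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


def filter_small_scaffolds(genome: Genome, min_genes: int) -> Genome:
    """Drop chromosomes/scaffolds carrying fewer than ``min_genes`` genes.

    Real assemblies contain unplaced scaffolds with a handful of genes each;
    these add noise to chromosome-tuple statistics.  Removal is logged.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    kept = {c: loci for c, loci in genome.chromosomes.items() if len(loci) >= min_genes}
    dropped = {c: len(loci) for c, loci in genome.chromosomes.items() if c not in kept}
    if dropped:
        logger.info(
            "%s: dropped %d scaffolds (<%d genes, %d genes total)",
            genome.species_id,
            len(dropped),
            min_genes,
            sum(dropped.values()),
        )
    if not kept:
        logger.warning("%s: no chromosomes remain after filtering", genome.species_id)
    return Genome(genome.species_id, kept)


@dataclass(frozen=True)
class Hit:
    bitscore: float
    evalue: float


@dataclass
class SimilarityHits:
    """Directed best-HSP similarity records keyed by (query, target)."""

    records: dict[tuple[str, str], Hit] = field(default_factory=dict)

    def add(self, query: str, target: str, bitscore: float, evalue: float) -> None:
        if bitscore < 0:
            raise IntegrityError(f"negative bitscore for ({query}, {target})")
        key = (query, target)
        prev = self.records.get(key)
        if prev is None or bitscore > prev.bitscore:
            self.records[key] = Hit(bitscore, evalue)

    def __len__(self) -> int:
        return len(self.records)

    def queries(self) -> set[str]:
        return {q for q, _ in self.records}

    def targets(self) -> set[str]:
        return {t for _, t in self.records}

    def by_query(self) -> dict[str, dict[str, float]]:
        """query -> {target: bitscore}."""
        out: dict[str, dict[str, float]] = {}
        for (q, t), hit in self.records.items():
            out.setdefault(q, {})[t] = hit.bitscore
        return out


def read_hits(path: str | Path) -> SimilarityHits:
    """Read a 12-column similarity-hit table, collapsing HSPs to max bitscore."""
    path = Path(path)
    hits = SimilarityHits()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 columns, got {len(fields)}",
                    path=str(path),
                    line=lineno,
                )
            query, target = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric evalue/bitscore: {fields[10]!r}, {fields[11]!r}",
                    path=str(path),
                    line=lineno,
                ) from exc
            hits.add(query, target, bitscore, evalue)
    return hits


def write_hits(hits: SimilarityHits, path: str | Path) -> None:
    """Write hits in the 12-column dialect (unused middle columns zeroed)."""
    with open(path, "w") as fh:
        for (q, t), hit in sorted(hits.records.items()):
            fh.write(
                f"{q}\t{t}\t100.0\t100\t0\t0\t1\t100\t1\t100"
                f"\t{hit.evalue:g}\t{hit.bitscore:g}\n"
            )
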