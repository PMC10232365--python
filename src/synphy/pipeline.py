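"""End-to-end orchestration: orthology -> macrosynteny -> linkage groups ->
mixing -> characters -> phylogeny -> shuffle test, from a single config.

Stages communicate only through declared file artifacts under the output
directory, so the pipeline is resumable and auditable; a manifest records
package version, seeds, thresholds, and SHA-256 checksums of every artifact.
Identical configs give identical manifests in single-threaded runs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .characters import build_character_matrix
from .errors import InputError
from .genome import Genome, filter_small_scaffolds, read_gene_map, read_hits
from .hyptest import shuffle_hypothesis_test
from .linkage import (AlphaTable, SyntenyGroup, identify_groups,
                      permutation_alpha, significant_groups)
from .macrosynteny import association_table, chromosome_association
from .orthology import nway_groups, reciprocal_best_hits
from .phylo import RateModel, mcmc_posterior, parsimony_search

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    species: dict[str, dict]  # id -> {path, role, format?}
    outdir: str
    hits_dir: str
    seed: int = 0
    alpha: float = 0.05
    localization_fraction: float = 0.8
    min_scaffold_genes: int = 10
    n_perm_linkage: int = 2000
    n_perm_shuffle: int = 10_000
    mcmc_generations: int = 100_000
    burn_in_fraction: float = 0.25
    shuffled_species: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        roles = [s.get("role") for s in self.species.values()]
        for sid, entry in self.species.items():
            p = Path(entry["path"])
            if not p.exists():
                raise InputError(f"genome path for {sid} does not exist: {p}")
        if self.shuffled_species and self.shuffled_species not in self.species:
            raise InputError(f"shuffled_species {self.shuffled_species!r} unknown")
        for role in ("outgroup",):
            if role not in roles:
                raise InputError(f"no species has role {role!r}")

    def role_map(self) -> dict[str, str]:
        return {sid: e["role"] for sid, e in self.species.items() if e.get("role")}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_groups_tsv(groups: set[SyntenyGroup], path: Path) -> None:
    rows = sorted(groups, key=lambda g: (-g.size_k, g.label))
    with open(path, "w") as fh:
        fh.write("label\tchrom_tuple\tk\talpha\tmembers\n")
        for g in rows:
            tup = ";".join(f"{s}:{c}" for s, c in g.chrom_tuple)
            members = ";".join(
                ",".join(f"{s}={gid}" for s, gid in og.items)
                for og in sorted(g.members, key=lambda o: o.items)
            )
            alpha = "" if g.alpha is None else f"{g.alpha:.6g}"
            fh.write(f"{g.label}\t{tup}\t{g.size_k}\t{alpha}\t{members}\n")


def write_alpha_tsv(table: AlphaTable, k_max: int, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("k\talpha\tn_perm\tseed\tscheme\n")
        for k, a in table.as_dict(k_max).items():
            fh.write(f"{k}\t{a:.6g}\t{table.n_perm}\t{table.seed}\t{table.scheme}\n")


def read_groups_tsv(path: str | Path) -> set[SyntenyGroup]:
    """Read a groups TSV written by :func:`write_groups_tsv`."""
    from .orthology import OrthoGroup

    out: set[SyntenyGroup] = set()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            label, tup_s, k, alpha_s, members_s = line.rstrip("\n").split("\t")
            tup = tuple(
                tuple(part.split(":", 1)) for part in tup_s.split(";")
            )
            members = frozenset(
                OrthoGroup(tuple(tuple(kv.split("=", 1)) for kv in og.split(",")))
                for og in members_s.split(";") if og
            )
            alpha = float(alpha_s) if alpha_s else None
            out.add(SyntenyGroup(label, tup, members, int(k), alpha))
    return out


def pairs_from_groups(
    groups: set[SyntenyGroup], genomes: Mapping[str, Genome]
) -> list[tuple[str, str, dict[str, set[str]], dict[str, set[str]]]]:
    """Candidate fusion characters: all pairs of synteny groups co-resident
    on one chromosome in at least one taxon."""
    glist = sorted(groups, key=lambda g: g.label)
    pairs = []
    for g1, g2 in itertools.combinations(glist, 2):
        c1, c2 = g1.chromosomes, g2.chromosomes
        if not any(c1.get(s) == c2.get(s) for s in c1):
            continue
        mem_x = {s: g1.member_genes(s) for s in genomes}
        mem_y = {s: g2.member_genes(s) for s in genomes}
        pairs.append((f"{g1.label}_x", f"{g2.label}_y", mem_x, mem_y))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "localization_fraction": config.localization_fraction,
            "min_scaffold_genes": config.min_scaffold_genes,
        },
        "stages": {},
        "checksums": {},
        "inputs": {},
    }

    def finish(stage: str, t0: float, *artifacts: Path) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "artifacts": [a.name for a in artifacts],
        }
        for a in artifacts:
            manifest["checksums"][a.name] = _sha256(a)

    # stage 1: genomes
    t0 = time.perf_counter()
    genomes: dict[str, Genome] = {}
    for sid, entry in config.species.items():
        g = read_gene_map(entry["path"], entry.get("format", "chrom"))
        g.species_id = sid
        genomes[sid] = filter_small_scaffolds(g, config.min_scaffold_genes)
        manifest["inputs"][sid] = _sha256(Path(entry["path"]))
    finish("genomes", t0)

    # stage 2: orthology (RBH + n-way cliques)
    t0 = time.perf_counter()
    species = sorted(genomes)
    hits_dir = Path(config.hits_dir)
    pair_maps = {}
    for a, b in itertools.combinations(species, 2):
        hits_ab = read_hits(hits_dir / f"{a}__{b}.hits.tsv")
        hits_ba = read_hits(hits_dir / f"{b}__{a}.hits.tsv")
        pair_maps[(a, b)] = reciprocal_best_hits(hits_ab, hits_ba)
    orthogroups = nway_groups(pair_maps, species)
    og_path = outdir / "orthogroups.tsv"
    with open(og_path, "w") as fh:
        fh.write("\t".join(species) + "\n")
        for og in sorted(orthogroups, key=lambda o: o.items):
            fh.write("\t".join(og.members[s] for s in species) + "\n")
    finish("orthology", t0, og_path)

    # stage 3: macrosynteny tables
    t0 = time.perf_counter()
    ms_path = outdir / "macrosynteny.tsv"
    frames = []
    for a, b in itertools.combinations(species, 2):
        assoc = chromosome_association(
            genomes[a], genomes[b], pair_maps[(a, b)], config.alpha
        )
        df = association_table(assoc)
        df.insert(0, "species_a", a)
        df.insert(1, "species_b", b)
        frames.append(df)
    import pandas as pd

    pd.concat(frames).to_csv(ms_path, sep="\t", index=False)
    finish("macrosynteny", t0, ms_path)

    # stage 4: linkage groups + permutation FDR
    t0 = time.perf_counter()
    groups = identify_groups(orthogroups, genomes)
    alphas = permutation_alpha(
        orthogroups, genomes, config.n_perm_linkage, config.seed
    )
    sig = significant_groups(groups, alphas, config.alpha)
    groups_path = outdir / "groups.tsv"
    alpha_path = outdir / "alpha_table.tsv"
    write_groups_tsv(sig, groups_path)
    k_max = max((g.size_k for g in groups), default=1)
    write_alpha_tsv(alphas, k_max, alpha_path)
    finish("linkage_groups", t0, groups_path, alpha_path)

    # stage 5: fusion characters (mixing verdicts inside the encoder)
    t0 = time.perf_counter()
    pairs = pairs_from_groups(sig, genomes)
    matrix = build_character_matrix(
        genomes, pairs, config.localization_fraction, config.alpha
    )
    chars_path = outdir / "characters.tsv"
    nexus_path = outdir / "characters.nex"
    matrix.write_tsv(chars_path)
    from .phylo import DEFAULT_STEPS

    matrix.write_nexus(nexus_path, DEFAULT_STEPS.cost, mrbayes_block=True)
    finish("characters", t0, chars_path, nexus_path)

    # stage 6: phylogeny (parsimony + MCMC)
    t0 = time.perf_counter()
    roles = config.role_map()
    outgroup = next(s for s, r in roles.items() if r == "outgroup")
    phylo_path = outdir / "phylogeny.json"
    result: dict = {}
    if len(matrix) > 0:
        ranking = parsimony_search(matrix, outgroup)
        result["parsimony"] = [
            {"tree": t.newick(lengths=False), "cost": c} for t, c in ranking[:10]
        ]
        result["parsimony_unique_optimum"] = (
            len(ranking) == 1 or ranking[0][1] < ranking[1][1]
        )
        post = mcmc_posterior(
            matrix,
            RateModel(),
            generations=config.mcmc_generations,
            burn_in_fraction=config.burn_in_fraction,
            seed=config.seed,
            outgroup=outgroup,
        )
        result["mcmc"] = {
            "map_tree": post.map_tree,
            "clade_posteriors": {
                "+".join(sorted(c)): p for c, p in sorted(
                    post.clade_posterior.items(), key=lambda kv: -kv[1]
                )
            },
            "generations": post.generations,
            "n_samples": post.n_samples,
            "acceptance": post.acceptance,
        }
    phylo_path.write_text(json.dumps(result, indent=1))
    finish("phylogeny", t0, phylo_path)

    # stage 7: hypothesis shuffle test
    t0 = time.perf_counter()
    shuffle_path = outdir / "shuffle_test.json"
    payload: dict = {}
    if config.shuffled_species and len(matrix) > 0 and set(roles.values()) >= {
        "outgroup", "ctenophore", "sponge", "cnibil"
    }:
        res = shuffle_hypothesis_test(
            genomes, pairs, roles, config.shuffled_species,
            config.n_perm_shuffle, config.seed,
            config.localization_fraction, config.alpha,
        )
        payload = {
            "observed": res.observed.__dict__,
            "alpha_cteno": res.alpha_cteno,
            "alpha_sponge": res.alpha_sponge,
            "null_hist_cteno": res.null_hist_cteno,
            "null_hist_sponge": res.null_hist_sponge,
            "n_perm": res.n_perm,
            "shuffled_species": res.shuffled_species,
        }
    shuffle_path.write_text(json.dumps(payload, indent=1))
    finish("shuffle_test", t0, shuffle_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d stages", len(manifest["stages"]))
    return manifest
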