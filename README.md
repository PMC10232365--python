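# synphy — chromosome-scale synteny phylogenetics

`synphy` infers deep animal phylogeny from the large-scale organization of
genomes rather than from sequence alignments.  The observation behind it:
gene content of chromosomes ("macrosynteny") is conserved over hundreds of
millions of years, and two kinds of rare chromosomal events leave
phylogenetically readable marks.  A **fusion** joins two ancestral linkage
groups (ALGs) onto one chromosome; while the two gene sets remain in
segregated blocks the fusion is reversible by fission.  Once subsequent
intrachromosomal rearrangement **mixes** the two gene sets, restoring the
ancestral separation is effectively impossible — fusion-with-mixing is an
irreversible, Dollo-like derived character.  Shared fusion-with-mixing
events are therefore near-perfect synapomorphies for resolving contested
branching orders such as whether ctenophores or sponges are the sister
lineage of all other animals.

The package implements the full analysis chain:

1. **Orthology** — one-to-one orthologues as reciprocal best bitscore hits
   (RBH) from precomputed similarity tables, extended to *n*-way orthogroups
   by requiring the full RBH clique across all species pairs; orthogroups
   from runs against different outgroups can be joined on identical
   anchor-species gene tuples.
2. **Macrosynteny** — chromosome homology between two species by one-sided
   Fisher's exact tests (upper hypergeometric tail) on the 2×2 table of
   orthologue placements, Bonferroni-corrected over the combinations
   actually tested; plot-ready ribbon/dot tables.
3. **Linkage groups** — orthogroups partitioned by the tuple of chromosomes
   they occupy across all species; the false-discovery rate α(k) of finding
   a co-resident set of size ≥ k is estimated by shuffling gene positions
   over each genome's fixed chromosome skeleton.
4. **Mixing** — for two gene subgroups on one chromosome, the number of
   adjacent x↔y transitions in rank order is compared with the exact
   Wald–Wolfowitz runs distribution; small lower-tail α means segregated
   ("unmixed", α < 0.05), large means mixed.
5. **Characters** — each ALG pair becomes a per-taxon state: 0 separate,
   1 fused-unmixed, 2 fused-mixed, ? unknown; quartet patterns classify
   characters as ancestral, autapomorphic, or shared-derived.
6. **Phylogeny** — Sankoff parsimony with an asymmetric step matrix
   (unmixing forbidden) over exhaustively enumerated rooted topologies, and
   Bayesian MCMC under a continuous-time 3-state model with the unmixing
   rate fixed at zero.
7. **Hypothesis test** — counts of characters supporting ctenophore-sister
   vs sponge-sister, with a genome-shuffling permutation null.
8. **Simulator** — genomes evolved along a known tree by translocation
   (default: 1% of genes per ~40 Myr), fusion, fission, mixing and
   fusion-with-mixing, with identity-preserving orthology and an exactly
   replayable event log, so the whole pipeline is testable end to end
   without any downloads.

## Worked example

Simulate five genomes (15 chromosomes × 400 genes) on a tree in which four
fusion-with-mixing events are planted on the stem of the
sponge+cnidarian+bilaterian clade, then run the whole analysis:

```python
from synphy import (SimRates, simulate_evolution, build_character_matrix,
                    parsimony_search, mcmc_posterior, RateModel)

tree = "(OUT:800,(CTE:700,(SPO:650,(CNI:550,BIL:550):100):50):100);"
planted = [("mrca_BIL_CNI_SPO", "fusion_with_mixing",
            {"chrom_a": f"anc{2*i+1}", "chrom_b": f"anc{2*i+2}"})
           for i in range(4)]
truth = simulate_evolution(tree, (15, 400), SimRates(), planted, seed=11)

# fusion characters over the known ancestral linkage units
anc = {c: {t: {truth.orthology[t][l.gene_id] for l in loci}
           for t in truth.leaf_genomes}
       for c, loci in truth.root_genome.chromosomes.items()}
pairs = [(f"anc{2*i+1}_x", f"anc{2*i+2}_y", anc[f"anc{2*i+1}"], anc[f"anc{2*i+2}"])
         for i in range(4)]
matrix = build_character_matrix(truth.leaf_genomes, pairs)
print(matrix.to_dataframe())

best, cost = parsimony_search(matrix, "OUT")[0]
print(best.newick(lengths=False), cost)

post = mcmc_posterior(matrix, RateModel(), generations=100_000,
                      seed=1, outgroup="OUT")
print(round(post.clade({"SPO", "CNI", "BIL"}), 3))
```

Output:

```
    anc1_x_anc2_y anc3_x_anc4_y anc5_x_anc6_y anc7_x_anc8_y
OUT             0             0             0             0
CTE             0             ?             0             0
SPO             2             2             ?             2
CNI             2             2             2             2
BIL             2             2             2             2
((((BIL,CNI),SPO),CTE),OUT); 8.0
0.997
```

The planted fusions are read back as state 2 in exactly the descendant taxa
(the two `?` entries are subgroups whose localization fell just below the
80% threshold after ~18% background translocation); the most parsimonious
topology is the true one (cost 8 = four fusion-with-mixing events at two
steps each), and the Bayesian posterior for the planted clade is 0.997.

The same analysis is scriptable from the shell:

```bash
synphy simulate --tree tree.nwk --outdir sim/ --seed 11
synphy run-all --config run.yaml
```

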