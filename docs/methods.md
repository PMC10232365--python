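# Methods

This note documents the models, statistics, numerical choices and known
limitations of `synphy`.  All statements of behaviour here are backed by the
test suite (`tests/`) or the acceptance script (`scripts/acceptance.py`);
nothing below reports a number the code does not itself compute.

## Data model and conventions

Gene positions are read from 5-column tables (`gene_id scaffold strand
start stop`, 1-based inclusive) or BED (0-based half-open, converted on
read).  Internally every statistic operates on **ranks** — the 0-based
order of genes along a chromosome after sorting by (start, gene_id) — never
on base-pair coordinates, because synteny is defined by co-residence
irrespective of gene order and spacing.  Strand is parsed, preserved, and
ignored by all statistics for the same reason.  Unplaced scaffolds can be
removed with `filter_small_scaffolds`; the default pipeline threshold is 10
genes (configurable, logged), since a handful-of-genes scaffold contributes
noise to chromosome-tuple statistics without evidential weight.

## Orthology

Pairwise orthologues are reciprocal best hits by **maximum bitscore** (not
minimum e-value; e-values are retained but unused by default).  A query
whose top bitscore is tied between targets is dropped entirely — a
conservative rule that avoids arbitrary one-to-one assignments.  *n*-way
orthogroups require the complete C(n,2) RBH clique, so every orthogroup has
exactly one gene per species; this loses genuine orthologues (duplicates,
asymmetric best hits) but keeps the downstream co-residence statistics
clean.  Orthogroups from runs that share an anchor trio of species are
joined when their anchor gene tuples are identical; conflicting non-anchor
assignments keep the first-seen gene, set a conflict flag, and are excluded
from character encoding by default.

## Macrosynteny tests

For each (chromosome A, chromosome B) combination with at least one shared
orthologous pair, the 2×2 table [on both / A only / B only / neither] over
all orthologous pairs is tested for enrichment with the one-sided upper
hypergeometric tail (scipy's `hypergeom.sf`).  The Bonferroni family size m
is the number of combinations actually tested (those with ≥ 1 shared pair),
which matches the set of computed tests; m is logged.  Only enrichment is
tested — conserved linkage, not depletion, is the object of interest.  The
test suite verifies the implementation against exact rational tail sums
(`fractions.Fraction` over `math.comb`) to 1e-12 on every table with
N ≤ 50.

## Linkage groups and the permutation FDR

Orthogroups are partitioned by the tuple of chromosomes their genes occupy
across the n species; each cell of that partition is a candidate conserved
linkage group of size k.  Significance is a permutation FDR: each in-scope
genome's gene identities are shuffled over its fixed chromosome skeleton
(per-chromosome gene counts preserved exactly), groups are re-identified,
and

    α(k) = (1 + #{permutations with any group of size ≥ k}) / (1 + n_perm).

The tail ("size ≥ k") definition makes α monotone non-increasing in k; the
+1 pseudocount keeps α in (0, 1].  An alternative expected-count scheme
(mean number of size-≥k groups per permutation) is available via
configuration.  Permutations are drawn from a single seeded generator in a
fixed species order, so runs are reproducible bit-for-bit.  Tests verify
α against exhaustive enumeration on tiny genomes (e.g. the two-species,
two-chromosome case whose exact joint co-residence probability is 1/9)
within three binomial standard errors at n_perm = 10⁴, and the degenerate
one-chromosome case where α(k) = 1 for all k.  Default n_perm is 10⁴–10⁵ at
desk scale; the statistic is embarrassingly scalable if smaller α floors
are needed.

## The mixing statistic

Two gene subgroups x and y co-resident on a chromosome are reduced to their
binary label sequence in rank order, ignoring intervening genes (only the
relative order of the subgroup genes is informative, and the null
randomizes exactly that).  The statistic is the number of adjacent label
transitions t.  Under uniform random interleaving of a x-genes and b
y-genes the number of runs r = t + 1 follows the classical two-sample runs
distribution:

    #(r = 2m)   = 2·C(a−1, m−1)·C(b−1, m−1)
    #(r = 2m+1) = C(a−1, m−1)·C(b−1, m) + C(a−1, m)·C(b−1, m−1)

normalized by C(a+b, a).  α = P(T ≤ t_obs) is the **lower** tail: a small α
means the arrangement is far more segregated than random interleaving would
produce, i.e. "unmixed".  The α < 0.05 ⇒ unmixed convention fixes the
verdict threshold; note that a + b must be ≥ about 9 before the minimum
possible t can reach significance at all, so small fused pairs are
conservatively called "mixed".  The closed form is used for a + b ≤ 2000;
beyond that a Monte-Carlo estimate with +1 pseudocount takes over
(n_perm = 10⁴ default).  Tests confirm exact/permutation agreement within
three binomial standard errors for all a + b ≤ 12.

## Fusion characters and quartet logic

For a pair of ALG subgroups in one genome, each subgroup is assigned its
majority chromosome.  If either majority fraction is below the
**localization fraction** (default 0.8) the state is `?` — subgroups
genuinely split by fission or assembly artefacts should abstain rather than
force a call.  Distinct majority chromosomes give state 0; identical ones
give 1 or 2 by the mixing verdict.  If both subgroups co-reside on more
than one chromosome, the chromosome with the largest joint membership is
scored (logged).

Quartet classification polarizes a character with an outgroup O and
ingroups A, B, C.  Any `?` is uninformative.  With O unfused: zero fused
ingroups is ancestral; one is an autapomorphy; two is a shared fusion
uniting those two taxa — counted as *fusion-with-mixing* (the irreversible,
strongest class) only when **both** are state 2, since mixing observed in a
single lineage may postdate the fusion; three fused ingroups is a stem
fusion, uninformative for ingroup branching.  With O fused: an all-unfused
ingroup is an outgroup-specific fusion or fission (uninformative); all
taxa fused is ancestral; other combinations conflict with a single origin.
The full 4⁴ truth table is locked against an independently hand-coded
oracle in the tests.

## Tree inference

**Parsimony.**  Sankoff dynamic programming with a 3×3 step matrix; `?` is
free at leaves; the root state may be fixed to 0 (ancestral separate) or
left free.  The default costs are fusion = fission = mixing = 1,
fusion-with-mixing within a single edge = 2, and unmixing (2→1, 2→0) = ∞.
Both fusion and fission are observed processes, hence the symmetric 0↔1
cost; irreversibility of the mixed state is the entropy argument — a mixed
chromosome fissions into two mixed fragments, not back into the two
ancestral gene sets.  Topologies are enumerated exhaustively (all
(2k−3)!! rooted-by-outgroup trees) for up to 9 taxa; the dynamic programme
is verified against brute-force minimization over all ancestral state
assignments.

**Bayesian MCMC.**  A continuous-time 3-state Markov model with free rates
for fusion (0→1), fission (1→0) and mixing (1→2); the unmixing rates are 0
by default, making state 2 absorbing (a small ε is configurable).  With
ε = 0 the transient 2×2 block is exponentiated in closed form via its real
eigenvalues (the discriminant (a+b+c)² − 4ac is provably non-negative),
with a series fallback near eigenvalue degeneracy and a generic
`scipy.linalg.expm` path when ε > 0.  The root, placed at the outgroup
attachment, is fixed to state 0 (outgroup polarization; configurable).
Priors: exponential(mean 1) on rates, exponential(mean 0.1) on branch
lengths, uniform over rooted topologies.  Proposals mix single-branch and
single-rate multiplier moves, rooted NNI (outgroup pinned), and — in the
enumerable ≤ 9-taxon regime — two global topology moves: an independence
jump (uniform topology with branch lengths, and optionally rates, redrawn
from the prior; the Hastings ratio reduces to the likelihood ratio) and a
Gibbs move that resamples the topology from its exact conditional over all
rooted topologies with branch lengths carried by postorder position.  The
global moves exist purely to decorrelate the topology indicator — the
chain's stationary distribution is unchanged, which the tests check by
recovering the exact uniform prior (every clade at 3/15) on a no-signal
matrix.  Likelihoods of zero (e.g. an irreversibility violation when the
root is forced to state 2) are proposed and rejected, never errors.  Runs
are single-threaded and bit-for-bit reproducible given the seed.

On the bundled seven-character five-taxon matrix (outgroup and ctenophore 0
throughout; demosponge 2,2,2,2,1,1,1; cnidarian and bilaterian 2
throughout), 100,000 generations with 25% burn-in give a posterior ≈ 0.99–1.0
for the demosponge+cnidarian+bilaterian clade (the acceptance script
recomputes this), and ctenophore-sister is the strict parsimony optimum
among all 15 rooted ingroup topologies at cost 14 vs 17 for the runners-up.

## Hypothesis support and the genome-shuffling null

A character supports ctenophore-sister when outgroup and ctenophore are
both 0 while sponge and the cnidarian/bilaterian representative are both
fused (≥ 1); sponge-sister support is the mirror pattern.  Group counts and
gene counts are both reported.  The null shuffles one species'
gene → position assignment over its chromosome skeleton and re-encodes only
that species' states per permutation (the other taxa are unaffected by
construction), with streaming aggregation so memory is O(1) in n_perm and

    α = (1 + #{permutations with support ≥ observed}) / (1 + n_perm).

Default n_perm is 10⁵ at desk scale; the per-permutation cost is a few
microseconds per candidate pair.

## The simulator

`simulate_evolution` evolves a root genome (default 15 chromosomes × 400
genes — a 6,000-gene chromosome-scale genome within the realistic
karyotype range for this problem) along a Newick tree with branch lengths
in Myr.  Translocation moves single genes to uniform positions on other
chromosomes; each gene moves over a branch of t Myr with probability
1 − exp(−λt), with the default λ = −ln(0.99)/40 chosen so that 1% of genes
move per 40 Myr — the empirical animal rate.  Fusion concatenates two
chromosomes; fission splits at a uniform internal boundary; mixing applies
k = 3 Gilbert–Shannon–Reeds riffle interleavings (partial mixing is
producible; large k approaches a full shuffle); fusion-with-mixing composes
the two.  Structural event rates default to 0 and controlled experiments
place them as *forced events* at branch midpoints — matching how rare
fusion events are used as planted, known-location signals; Poisson
background rates are available for all event kinds.  Every sampled event is
recorded with concrete parameters, so the log replays deterministically and
the test suite asserts exact leaf-genome reproduction.  Gene ids survive
all events, giving identity orthology; emitted pairwise hit tables give
each shared gene a strong true hit plus a weak random decoy so RBH logic is
genuinely exercised.

What the simulator does **not** emulate: sequence evolution (orthology
inference from real alignments is noisier than the decoy scheme), gene
family birth/death beyond single-gene gain/loss, whole-genome duplication,
assembly error, and unplaced scaffolds.  Passing recovery tests therefore
demonstrate correctness of the statistical chain, not robustness to
annotation or assembly artefacts.

## Known limitations

* **Chance translocation clusters.**  At full gene density (every gene an
  orthologue), independent translocations from chromosome i to chromosome j
  in one lineage accumulate into co-resident clusters of 4–9 genes over
  ~800 Myr.  These pass the co-residence FDR (they are genuinely linked in
  all species) and, paired with one another, can mimic informative
  patterns: discovery-mode character building
  (`pairs_from_groups`, all co-resident pairs of significant groups) on
  dense simulated data therefore contains spurious low-weight characters.
  Topology recovery is robust to them (they are symmetric noise), but
  hypothesis support counts are cleanest when candidate pairs come from an
  established ALG table — which is also how the analysis is run on real
  data.  At realistic orthologue densities (a few thousand n-way
  orthogroups spread over 20–36 chromosomes) such clusters are rare.
* The α floor of any permutation test is 1/(n_perm + 1); claims like
  "never observed" are bounded accordingly.
* The MCMC topology moves specialise to ≤ 9 taxa; beyond that only
  branch/rate/NNI moves operate and convergence should be checked across
  seeds.
* Bonferroni correction is per species pair; no correction is applied
  across mixing tests (an optional Benjamini–Hochberg flag exists but is
  off by default, matching standard practice for this analysis).
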