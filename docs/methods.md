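# Methods

## Study design

The package implements a controlled experiment on orthology inference.
Ground truth is manufactured: single-copy protein families evolve along a
known rooted guide tree with substitutions only — no indels, duplications,
gains, losses, or horizontal transfer — so the correct orthogroup
partition is known exactly (one orthogroup per family, each spanning every
species). An orthology engine then re-infers orthogroups from the leaf
sequences, and the inferred partition is pushed through the three standard
downstream analyses of orthogroup presence/absence data. Every deviation
from the truth in those outputs is, by construction, inference error.

## Guide tree

`generate_guide_tree` grows a random rooted bifurcating topology by
sequential random attachment (each new leaf splits a uniformly chosen
existing branch), which samples labelled topologies uniformly. Branch
lengths are i.i.d. log-normal with median 0.05 expected substitutions per
site and σ = ln(10)/1.96, putting ~95% of draws in [0.005, 0.5] — strongly
heterogeneous branch lengths on purpose, since rate-dependent error is the
object of study. Multifurcating input trees are accepted by the metrics
but not generated. Zero-length branches are legal on input; the generator
never draws them.

## Replicate design

Each replicate r of an experiment carries:

| parameter | law | default |
| --- | --- | --- |
| gene-rate multiplier m | log-uniform | [0.2, 10] |
| gamma shape α | log-uniform | [0.2, 2.5] |
| genes per replicate | fixed | 60 (desk), 5000 (study scale) |
| sequence length (aa) | log-normal, median 200, σ=0.35 | truncated below at 50 by resampling |

One multiplier and one α are shared by all genes of a replicate; lengths
are per-gene and constant along the tree. The multiplier endpoints are the
scaled-tree range of the study design; the α bracket spans strong
heterogeneity (0.2) to near-uniform rates (2.5) around the empirically
typical ~0.7. Log-uniform laws give even coverage of the rate axis.
Replicate seeds are derived as SeedSequence(master, replicate_id) reduced
below 2³¹; family seeds are counter-based, `[replicate_seed,
family_index]`, so any family is reproducible in isolation and parallel
execution is bit-identical to serial.

## Sequence simulation

Sites evolve independently under a reversible 20-state continuous-time
Markov chain. Q = R·diag(π) with symmetric exchangeabilities R and
stationary frequencies π, normalized so −Σ πᵢQᵢᵢ = 1 (branch lengths in
expected substitutions per site). Transition matrices come from one
symmetric eigendecomposition of diag(√π)·Q·diag(1/√π), so per-site scaled
exponentials cost one vector of eigenvalue exponentials per site.

Presets:

- **poisson** — equal exchangeabilities, uniform frequencies. Exists for
  closed-form testing: on one branch of length t the probability a site
  differs is (19/20)(1 − e^{−(20/19)t}).
- **blosum62** (default) — an empirical-flavoured matrix constructed at
  runtime from the BLOSUM62 half-bit log-odds table B: exchangeabilities
  r_ij = 2^{B_ij/2} (the implied odds ratios p_ij/(f_i f_j)), and
  background frequencies recovered from the log-odds consistency relation
  Σ_j f_j 2^{B_ij/2} = 1, solved as a linear system (all solutions are
  positive; they are clipped at 10⁻⁶ and renormalized defensively). This
  is the package's own construction, chosen because it requires no shipped
  rate-table data; it yields realistic non-uniform frequencies
  (f ranges ~0.012–0.090) and amino-acid-specific substitutibility.

Among-site rate variation is continuous gamma: rates i.i.d. Γ(shape α,
mean 1), drawn once per family, not discretized into categories. Site i on
a branch of length b evolves for time b·rateᵢ. The root sequence is drawn
from π. No rate drift along branches (no heterotachy) and no site-category
mixtures: rate and α are the two axes under study and both are
represented; covarion-like effects are out of scope.

**No indels** are simulated, so family members stay aligned by
construction. Consequence and fidelity limitation: the engine's alignment
stage sees gap-free homologs, making its task slightly easier than on real
proteins; observed error rates are therefore conservative.

## Orthology engine

A deliberately transparent stand-in for graph-based orthology pipelines;
every threshold is exposed in `EngineConfig`:

1. **k-mer prefilter** — a pair is aligned only if it shares ≥ 3 distinct
   exact 5-mers (computed for all pairs at once as a sparse gene×k-mer
   incidence product). This seeding heuristic is itself the mechanism by
   which fast-evolving orthologs are silently lost, mirroring the seed
   stage of fast similarity search tools.
2. **Scoring** — Smith–Waterman local alignment, BLOSUM62, gap open 11 /
   extend 1 (numba-compiled). Self-scores use the gap-free diagonal sum,
   which is optimal for a standard log-odds table.
3. **Normalization** — s(a,b) = raw(a,b)/√(raw(a,a)·raw(b,b)), clipped to
   [0, 1]; edges kept if s ≥ 0.05. Simpler than length-regression
   normalizations but monotone in identity, which is all the experiment
   needs.
4. **Best-hit filter** — for gene g and species S, hits within factor
   β = 0.9 of g's best score into S survive, required in both directions.
   Within-species hits participate (paralog-free input cannot merge
   families through them; they are kept for realism of the clustering
   input).
5. **MCL** — expansion (matrix squaring) alternated with inflation
   (entrywise power 1.5, column renormalization) on the column-stochastic
   similarity matrix with unit self-loops (standard practice; prevents
   period-2 oscillation on bipartite-like graphs). Iteration stops when
   the matrix changes by < 10⁻⁶ (max 100 iterations; non-convergence is
   flagged on the result, never raised). Clusters are the connected
   components of the converged matrix; genes with no surviving edges are
   singleton orthogroups.

Determinism: genes are sorted by (species, family index) before
clustering; best-hit ties share the best score and are co-retained.
Singletons count as orthogroups in both the orthogroup count and the mean
orthogroup size (the alternative convention can be read off
`frac_singletons`).

## Downstream analyses

**Presence/absence tree.** The binary species × orthogroup matrix (1 =
≥ 1 member) is reduced to Jaccard dissimilarities d(a,b) = 1 −
shared/(n_a + n_b − shared); Jaccard rather than Hamming because the
column count varies by orders of magnitude with fragmentation and Jaccard
conditions on presence. Neighbor joining (standard Q criterion,
lexicographic tie-breaking, negative branch estimates clamped to zero with
a counter) replaces likelihood tree search: it is deterministic, fast, and
consistent on additive inputs; the matrix can be exported in relaxed
PHYLIP binary for external ML programs. Accuracy is the unrooted
Robinson–Foulds distance to the guide tree. A matrix whose off-diagonal
distances are all equal (e.g. the all-ones matrix of a perfect run)
carries no signal: the replicate is flagged `degenerate_matrix` and its RF
recorded at the ceiling 2(n−3) — the score of a fully resolved tree
sharing no splits, which is what forcing a tree through a signal-free
matrix effectively produces — rather than pretending a meaningful tree was
built.

**Dollo gain/loss map.** Each orthogroup is gained exactly once, at the
MRCA of its species set (all-present columns gain at the root), and lost
on the branches to the maximal all-absent subtrees inside the gain clade —
the unique minimum-loss single-gain scenario. Pure Dollo is used instead
of gain-penalty parsimony or probabilistic birth–death rates: the
downstream analyses being emulated frame history as origin-plus-losses,
and the exhaustively enumerable optimum makes the mapping testable. Total
gains always equal the column count; since the simulation contains zero
losses, the entire loss map is artifact.

**Phylostratigraphy.** Strata are the nodes on the root-to-focal-leaf
path, rank 1 at the root and rank D at the focal terminal (D = number of
path nodes). A focal gene's age is the rank of the smallest stratum whose
leaf set contains its orthogroup's species set — equivalently the path
position of the MRCA of members plus focal. Unclustered focal genes get
rank D (a search that finds no homolog outside the focal species calls the
gene lineage-specific). AGA is the arithmetic mean rank over focal genes;
the focal species defaults to the lexicographically first leaf.

## Problem sizes

Desk-scale defaults (24 species, 20 replicates, 60 genes, length median
200) complete in minutes on one CPU; the tests' shared runs use 57
species × 30 genes for the zero-error reference and a 24-species,
20-gene rate ladder {0.2, 2, 5, 10} × 3 seeds at α = 0.7 for the
directional results. Study scale (57 species, 200 replicates, 5000 genes)
is reachable through the same `ExperimentDesign` by overriding counts.

## Numerical and degenerate-input choices

- Transition-probability rows are clipped at 0 and renormalized (guards
  eigendecomposition round-off at tiny times).
- MCL entries below 10⁻¹² are pruned each iteration to preserve sparsity.
- Normalized similarity is capped at 1 (cross-scores can marginally exceed
  the geometric self-score mean for near-identical pairs).
- Spearman correlations use midranks; a constant vector yields NaN
  (flagged) rather than an exception.
- Zero-length branches are identity maps; a species with zero presences
  makes Jaccard undefined and raises, naming the species.
- Replicates are failure-isolated: an exception marks the row `failed`
  with the message, and the experiment continues (the CLI exits non-zero
  if any replicate failed).

## What passing tests do and do not show

The generator emulates the statistical *structure* of the study — rate
scaling of a fixed tree, per-replicate α, single-copy families everywhere
— not real proteomes: no indels, no compositional drift, no paralogy, no
missing data, a single substitution matrix rather than site-category
mixtures, and a synthetic guide tree rather than an estimated one.
Directional results (error rising with rate and α, losses inferred where
none occurred, shared-orthogroup counts anticorrelated with patristic
distance, AGA rising with rate) transfer to that idealized regime only;
absolute magnitudes (orthogroup counts, RF values) are engine- and
scale-specific by design. At desk scale the highest ladder rate (10×) is
still on the informative flank of the error curve for this tree depth —
near-total fragmentation, where presence/absence trees collapse again,
begins beyond it.
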