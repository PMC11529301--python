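# Methods

This note documents the models and procedures implemented in `catrer`, the
defaults and why they were chosen, the numerical details, and what the
synthetic-data tests do and do not demonstrate.

## Data model

A **master tree** is a rooted phylogeny whose branch lengths represent
average genome-wide evolutionary rates. Branches are identified by their
child node; because input Newick carries no internal labels, internal
identity is defined by the branch's child clade (the set of tip labels below
it), which makes branch bookkeeping stable across files that write the same
topology in different node orders. The `BranchIndex` lists branches in a
canonical post-order (children sorted by their smallest tip label), so the
RER matrix rows are reproducible bit-for-bit across runs and platforms.

**Gene trees** must equal the master topology restricted to the species
present in the gene. Validation prunes the master to the gene's tip set
(summing lengths over collapsed paths) and compares clade sets; genes that
conflict, contain foreign tips, or have fewer than 3 tips are reported and
skipped. When a master path is collapsed in a pruned gene tree, the gene
branch's full length is attributed to the child-most master edge of the
path, which conserves each gene's total tree length in the mapped vector.
Trees are used as rooted exactly as written — the CTMM likelihood is
root-dependent — and Newick is emitted with 10 significant digits so
read/write round-trips are stable.

## Relative evolutionary rates

For gene *g* with branch-length vector *x<sub>g</sub>* on the master branch
set:

1. **Scale normalisation.** *x<sub>g</sub>* is divided by its least-squares
   projection scale onto the genome-wide expectation, making RERs exactly
   invariant to each gene's overall rate.
2. **Expectation.** The per-branch expected length is the mean of the
   scale-normalised columns, iterated with the scale step to a fixed point
   (at most 20 rounds, max relative change < 1e−6). With proportional genes
   the iteration converges in one step.
3. **Transform and winsorization.** Both the gene vector and the expectation
   are square-root transformed (variance stabilisation for length-like
   quantities) and winsorized at 3 values per tail (per gene), which blunts
   single-branch outliers. Winsorization is applied after the transform and
   before the regression.
4. **Weighted regression and standardisation.** Residuals come from a linear
   regression of the transformed gene vector on the transformed expectation.
   Per-branch variances are estimated from the cross-gene spread of a first
   unweighted pass, floored at their 5th percentile (no infinite weights),
   normalised to unit mean, and used both as inverse-variance regression
   weights and to standardise the residuals (each residual divided by the
   estimated branch standard deviation). The standardisation matters:
   branch-length noise is multiplicative, so raw residual variance grows
   with branch length, and rank tests on unstandardised residuals are
   anti-conservative for phylogenetically coherent branch groupings. With
   equal branch variances the weighted and unweighted residuals coincide.

Genes with fewer than 10 species are dropped by default (configurable);
missing branches stay missing in the RER matrix and are dropped per gene at
test time, never imputed.

## CTMM ancestral reconstruction

Trait evolution follows a continuous-time Markov model with generator Q
(non-negative off-diagonals, zero row sums); the transition kernel is
P(t) = expm(Qt), computed through an eigendecomposition when it reproduces
`scipy.linalg.expm` to 1e−10 at a reference time and falling back to `expm`
otherwise. Rate models tie the off-diagonal entries: ER (1 parameter), SYM
(K(K−1)/2), ARD (K(K−1)), or any custom index matrix with gap-free indices.

The likelihood of the observed tip states is computed by Felsenstein
pruning with per-node scaling. Fitting maximises the likelihood over
log-rates (positivity by construction, hard bounds 1e−8..1e4) with L-BFGS-B
from 6 starts: a deterministic start at 1/tree-height plus 5 seeded
log-uniform draws on [1e−3, 10]/tree-height; rate surfaces can be multimodal
and the multi-start is cheap. When a ladder of nested models is fitted
(`rate_model="auto"`: ER → SYM → ARD), each more complex fit additionally
starts from the simpler optimum expanded to its parameterisation, which
guarantees a non-negative likelihood-ratio statistic. Model selection uses
the LRT with χ² df = difference in free parameters at α = 0.05, keeping the
simpler model unless rejected.

Ancestral states are **marginal** posterior probabilities from two-pass
(inside/outside) conditioning on all tips; a joint (max-product) mode is
available behind a flag. The root prior is flat by default (recorded in the
output; stationary-of-Q̂ and user-supplied priors are options). ML-state ties
break toward the lowest category index in registry order. Every branch is
labelled with the ML state of its child node (tips keep their observed
state): a branch's rate accrues on the lineage ending at the child.
Zero-length branches get an identity transition matrix and need no further
special-casing. Transition counts report, per unordered category pair, the
number of edges whose endpoint ML states differ.

## Per-gene association tests

Default: Kruskal–Wallis omnibus test (tie-corrected H, χ² p with K−1 df)
with effect size ε² = H/(n−1), where n is the number of branches used;
post hoc Dunn Z tests on mean-rank differences with tie-corrected variance,
positive Z meaning the first category of the pair (registry order) has the
larger mean rank. Dunn p-values are two-sided and adjusted across the
K(K−1)/2 pairs within each gene by Benjamini–Hochberg (Holm available); the
adjustment choice is recorded in the configuration because different
conventions exist. The parametric alternative is one-way ANOVA with
η² = SS_between/(SS_between+SS_within) and Tukey HSD post hoc tests.

Genes need at least 2 branches per category (default) after dropping
missing RERs, else they are skipped with a reason. Both terminal and
internal branches enter the groups — that is the point of reconstructing
internal states.

## Permulations

Parametric p-values treat branches as exchangeable; shared phylogenetic
history breaks that. The permulation null preserves it. Each draw:

1. **Rejection sampling.** Tip states are simulated from the fitted CTMM
   down the master tree (root from the prior). A draw is accepted when every
   category's extant count is within ceiling(r × observed count) of the
   observed count; r = 0 demands exact equality, r = 1 accepts anything.
   The relaxation r trades acceptance rate against exactness — the cost of
   exact matching grows steeply with the number of categories, and a small
   relaxation (0.1) speeds sampling greatly with little effect on the
   phenotype structure. Simulation is vectorised in geometrically growing
   batches; the per-draw attempt budget defaults to 100 × N.
2. **Internal permutation.** The observed reconstruction's internal-state
   multiset is placed on the internal nodes in uniform random order.
3. **Annealing.** A swap search re-organises internal states to fit the
   simulated tips: proposals swap two internal nodes with differing states;
   improvements in the full-labeling log-likelihood (edge transition
   probabilities × root prior) are always accepted, worsenings with
   probability exp(Δ/T). T starts at 1 and is multiplied by 0.95 after each
   sweep of (#internal nodes) proposals, for min(100 sweeps, 10,000
   proposals); the best labeling visited is returned, so the result is never
   worse than the input and the internal multiset is conserved throughout.
   On small trees the search attains the exhaustive-arrangement optimum in
   ≥ 95% of runs (tested). The proposal/schedule design is this package's
   own choice among reasonable annealing variants.

Each of the N draws uses an independent child RNG spawned from the
configured seed, so a `PermulationSet` is bit-reproducible. Per-gene null
statistics are computed efficiently by ranking each gene's RERs once and
re-aggregating rank sums under every null labeling.

**Empirical p-values** are the proportion of null effect sizes at least as
extreme as the observed one — one-sided (≥) for omnibus effect sizes,
two-sided by absolute value for signed post hoc statistics. A zero
proportion is flagged and displayed as "< 1/N"; no add-one correction is
applied by default (available by flag). Granularity is 1/N.

## Pathway enrichment

Genes are ranked by −log10 omnibus p (one-sided) or by signed −log10
adjusted post hoc p (pair mode, most positive first; ties break by gene id).
Enrichment is a Wilcoxon rank-sum test of member vs non-member scores (exact
for small tie-free samples, normal approximation otherwise), one-sided
toward high scores in omnibus mode and two-sided in pair mode, BH-corrected
across pathways. Pathways are intersected with the scanned genes and bounded
to [10, 500] members by default; unscanned genes are dropped, not treated as
low-ranked. Fold-enrichment curves plot, at each rank k, (members in top
k / k)/(pathway size / total) — exactly 1 at k = total — with a barcode of
member positions.

Permulated enrichment pushes every null labeling's gene scores through the
same standardised rank-sum statistic and compares the observed statistic
against that null (matching sidedness). This is what corrects for rank
clustering: genes with correlated evolutionary histories (e.g. a
co-regulated family) move through the ranking together, which inflates the
independence-assuming parametric test but inflates the permulation nulls
equally.

## Site screen

For each alignment column, the set of amino acids per category is collected,
ignoring species with a gap at the site. Between-category similarity is the
minimum pairwise Jaccard index over non-empty category sets (mean-Jaccard
available; the choice is printed in output). Sites at or below the threshold
are annotated with a clade-independence score: for the most invariant
(smallest-set) category, the presence/absence of its residues across all
ungapped species is run through Fitch small parsimony on the species tree,
and the minimum change count is reported as the number of independent
origins. One origin means the compositional difference traces to a single
clade (flagged as confounded); ≥ 2 origins indicates convergence. The
similarity score and threshold are explicit configuration — no canonical
values exist — and alignment coordinates are 1-based, with a reference-row
ungapped coordinate reported when a reference species is named.

## Synthetic data

The generator provides ground truth for every stage:

- `random_tree`: a uniform-split (pure-birth) rooted topology with i.i.d.
  exponential branch lengths (mean 0.05 by default, a typical genome-wide
  substitutions-per-site scale).
- `simulate_phenotype_on_tree`: a CTMM trait history returning both tip
  phenotypes and true internal states; by default it redraws until every
  category has ≥ 2 tips so K-group tests are well posed on the realised
  data.
- `simulate_gene_trees`: gene g's length on branch b is master_b ×
  scale_g × noise_gb, times a multiplier when g is affected and b's true
  state is the target category. Defaults: lognormal gene scale (sd 0.5),
  lognormal branch noise (sd 0.3), multiplier 3 on 10% of genes —
  a moderate, detectable planted effect over realistic per-branch noise.
- `simulate_correlated_blocks`: trait-independent genes where blocks share
  one per-branch noise vector (sd 0.4) over individual noise (sd 0.15),
  emulating families whose association ranks cluster.

What passing tests show: the likelihood machinery is exact (brute-force
oracles), the permulation constraints hold by construction, null gene-level
permulation p-values are uniform, planted rate shifts are recovered
(AUROC ≥ 0.9 at multiplier 3), and correlated null blocks that fool the
parametric enrichment test do not fool the permulated one. What they do not
show: behaviour under gene-tree estimation error, alignment error,
model-misspecified trait evolution (the generator and the fitted model share
the CTMM family), non-multiplicative rate noise, or real lineage-specific
effects. Test problem sizes (40–100 species, 200–500 genes, 100–200
permulations) were chosen as the smallest that make the statistical checks
stable; real analyses typically use thousands of genes and 10,000
permulations (10,000 nulls resolve empirical p down to 1e−4).

## Numerical details and edge cases

- Likelihood underflow is handled by per-node scaling in the pruning pass;
  impossible data return −inf rather than raising.
- Transition matrices are clipped to [0, 1] and row-renormalised after the
  matrix exponential to absorb rounding.
- A rate driven to the lower bound (e.g. identical tip states) is reported
  as a boundary fit, not an error.
- Degenerate statistic inputs return their limiting values: identical
  groups give H = 0/p = 1, zero within-group variance gives η² = 1 and
  p = 0.
- All RNG flows through `numpy.random.Generator` seeded from explicit
  integers; per-draw generators are spawned via `SeedSequence` so
  parallel-order changes cannot silently alter results.

## Known limitations

- The rejection sampler's acceptance rate falls steeply as categories are
  added or the fitted rates make the observed counts atypical; the
  relaxation parameter is the intended mitigation, and exhaustion raises an
  explicit error suggesting it.
- Permulated enrichment is implemented for the omnibus ranking; pair-mode
  permulated enrichment would require per-draw post hoc adjustment choices
  that are not standardised here.
- The annealing step optimises a likelihood greedily-with-noise; it is a
  heuristic and is validated only against exhaustive search on small trees.
- Branch labels are hard (ML state of the child); reconstruction uncertainty
  is available in the posterior probabilities but is not propagated into the
  gene tests.
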