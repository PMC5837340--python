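# Methods

## Problem and scope

When a Bayesian phylogenetic analysis coestimates topology and divergence
times from morphological data, the posterior sample of trees is typically
diffuse: small character matrices carry little information, so the MCMC
visits many distinct topologies. A single consensus tree must then stand in
for the whole sample. `cladesum` implements and evaluates the three common
summaries —

* **MCC** (maximum clade credibility): the sampled tree maximizing the sum
  (default) or product of its clades' posterior probabilities;
* **MAP** (maximum a posteriori): the most frequently sampled topology;
* **MRC** (majority-rule consensus): exactly the clades with posterior
  probability > 0.5, with soft polytomies elsewhere —

by simulating binary matrices on a known time tree, inferring posterior
samples with a tip-dated strict-clock MCMC, and counting how many clades of
each consensus tree are right or wrong relative to the generating tree.

## Clades, not splits

All trees here are rooted time trees, so every nontrivial bipartition
corresponds to a rooted clade (a tip subset subtended by an internal node).
All bookkeeping — support tables, consensus construction, accuracy — uses
rooted clades. The root clade (all tips) is included everywhere: it is
trivially correct, and including it makes a fully resolved rooted 36-tip
tree contribute exactly 35 clades, the natural denominator for percentage
summaries. Singleton clades are never stored.

## Synthetic data

`simulate_serial_tree` draws a birth–death tree forward in time (default
birth 1.0, death 0.4 per lineage per unit time) until the requested number
of extant lineages is simultaneously alive; the requested number of fossil
tips is then drawn uniformly from the extinct lineages, the rest are
pruned, and ages are rescaled so the root sits at the target age (default
1.0, matching the root calibration used in inference). The default
configuration — 32 extant + 4 fossil tips, root age 1 — is the study
condition for the replicate experiments. The fossil-sampling rule (uniform
choice among extinct lineages) is a modelling decision; any user-supplied
Newick time tree can be substituted for the generated one.

`simulate_mk_matrix` evolves independent binary characters down the tree
under the 2-state Mk model with a strict clock: uniform root state, and
probability of an unchanged state after duration *t* of
½ + ½·e^(−2μt). Invariant characters are retained — no ascertainment
filter is applied — and the inference model is likewise plain Mk, so
simulation and inference are internally consistent. The default simulation
clock rate is μ = 1.0 change per character per unit time, which on a
root-age-1 tree yields matrices that are informative but far from
saturating — the regime in which consensus methods disagree.

`perturbation_sample` provides posterior-like tree samples without MCMC:
each draw applies a Poisson(diffusion) number of random NNI moves to a
focal tree and re-draws internal node ages. It exists for fast,
controlled testing of the consensus and evaluation machinery; it is not a
posterior.

## Inference model

`TipDatedMkModel` is a Model/Results pair in the statsmodels style:
`fit()` runs a Metropolis–Hastings sampler and returns `MkMcmcResults`
carrying the tree sample, the parameter trace, acceptance rates,
`summary()`, and consensus constructors.

Likelihood: Felsenstein pruning under the symmetric 2-state model, uniform
root frequencies, branch duration × clock rate giving expected change. An
empty matrix has log-likelihood 0, which turns the sampler into an exact
prior sampler — used by the prior-recovery checks.

Priors:

* clock rate ~ Gamma(shape 1, rate 2) (mean 0.5) — the shape/rate reading
  of the usual clock-prior convention;
* root age ~ Gamma(mean 1, sd 0.1), i.e. shape 100, rate 100;
* topology uniform over labelled rooted topologies;
* internal node ages given the root: a recursive-uniform construction —
  in preorder, each non-root internal age is uniform between the oldest
  tip age in its subtree and its parent's age. This is a proper density
  whose root-age marginal is exactly the root calibration, which is what
  makes prior recovery a sharp test.

Tip ages are errorless point calibrations and never move.

Moves: NNI (child–sibling swap at a random internal non-root node, with
the node's age redrawn uniformly in its new valid window; Hastings ratio =
ratio of window widths), node-age slide (uniform redraw between the oldest
child and the parent; symmetric), root-age slide (uniform window 0.1,
rejected below the oldest child), and a clock-rate multiplier (log-scale
window λ = 2.5, chosen for acceptance near 0.4 on prior-only runs).
Default mixture weights 0.4 / 0.35 / 0.15 / 0.1. Optional Metropolis
coupling runs `n_chains` incrementally heated chains (β = 1/(1 + 0.1·i))
with one random adjacent-pair swap proposal per generation; only the cold
chain is sampled. The default is a single chain: coupling is a mixing
device, not part of the estimand.

Defaults: 200,000 generations, sampled every 100, 25% burn-in (floor-based
on the stored sample count). All randomness flows from one integer seed;
runs are bit-reproducible.

## Consensus construction

`build_clade_table` counts clade frequencies over post-burn-in trees.
MCC rescoring is exhaustive over the sampled trees; ties break to the
earliest sample index. MAP topologies are equivalence classes by clade
set; ties break by MCC-sum credibility, then earliest index. MRC keeps
clades with pp strictly > 0.5 (a clade at exactly 0.5 is excluded) —
majority clades are pairwise compatible, so they assemble uniquely into a
tree by nesting each clade under its smallest strict superset.

`annotate_ages` marginalizes clade ages the way tree annotation tools do:
for each consensus clade, ages are collected from exactly the sampled
trees containing that clade; the summary reports the mean (median
optional), the shortest-interval 95% HPD, and the contributing-tree
count. Because different clades draw on different subsets of trees, the
mean ages can invert a parent–child pair; such implied negative branches
are reported in `negative_branches` and deliberately not repaired — this
is a real artefact of per-clade marginalization, not a bug.

## Accuracy scoring

A consensus clade is correct iff its tip set is exactly a clade of the
generating tree. Percentages divide by the consensus tree's own clade
count (root included), so MRC trees are judged against their own
resolution — a partially resolved MRC tree with no wrong clades scores 0%
incorrect regardless of how much it leaves unresolved. The overall score
is `n_correct − n_incorrect`. The valid-but-unrepresented scan flags
sampled clades whose pp exceeds (i) the weakest clade in the target tree,
(ii) the mean pp of the target's clades, or (iii) 0.5, yet are absent
from the target; the root clade is left out of the min/mean statistics
since its pp is 1 by construction.

## Problem sizes used by the test suite and acceptance script

The replicate experiments are deliberately small — a full-scale analysis
of this design (hundreds of replicates, 10^6-generation chains, matrices
up to 10,000 characters) is far beyond desk scale — and were chosen once
as the package's standard battery:

* diffuse regime: 36 tips (4 fossil), 100 characters, 10 replicates;
* concentrated regime: same tree design, 1,000 characters, 5 replicates;
* high-information check: 6 tips (1 fossil), 10,000 characters, 5
  replicates;
* chains of 40,000 generations, sampled every 20, 25% burn-in → 1,500
  post-burn-in trees per replicate;
* prior recovery: 200,000 generations on a zero-character matrix.

At these sizes the qualitative results are stable across seeds: unique
sampled clades drop by well over a factor of three from 100 to 1,000
characters; mean percentage of incorrect nodes orders MRC < MCC < MAP on
the diffuse regime; several MCC/MAP replicates (and rarely or never MRC)
have negative scores; and all methods are essentially error-free at high
information. Absolute values (e.g. the mean unique-clade count) depend on
the particular generating tree, the simulation clock rate and the chain
length, and are expected to differ from any one full-scale study.

## What the simulations do not capture

The generator produces complete, independently evolving binary characters
under the exact model the sampler assumes. Real morphological matrices
have missing data, correlated characters, ascertainment toward variable
characters, and model misspecification; passing these tests shows the
estimators and summaries behave as designed under the model, not that the
model fits real data. Divergence-time *accuracy* is not assessed — only
topology is scored; clade ages are summarized but never compared to truth.

## Numerical and degenerate-input choices

* Pruning works in linear space; with ≤ a few hundred tips the per-site
  likelihood stays well inside double range.
* Burn-in counts are floored; a burn-in that empties the sample raises.
* HPD uses the empirical shortest window containing ⌈0.95·k⌉ of k values.
* 2-tip trees yield only the root clade; `extract_clades` handles them.
* `count_rooted_topologies` is exact integer arithmetic ((2n−3)!!).
* Newick writing clamps infinitesimally negative branch lengths (float
  round-off) to zero; annotated consensus trees are written through a
  separate path that preserves negative branches.

## Known limitations

* Binary characters only; no rate heterogeneity, no relaxed clocks, no
  fossilized-birth-death tree prior.
* The MCMC proposal set is minimal (no subtree-prune-regraft), so very
  large trees mix slowly; the experiment sizes above were chosen with
  this in mind.
* MAP estimation by sample frequency is the standard finite-sample proxy;
  with highly diffuse posteriors most topologies are sampled once and the
  MAP tie-break (MCC-sum score) effectively decides.
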