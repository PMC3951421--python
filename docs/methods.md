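# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind dyphylo, in the order the analysis runs.

## Character matrices

Input is a taxa × characters grid over {0, 1, ?}, stored as int8 with −1 for
missing. NEXUS reading is liberal (DATA or CHARACTERS blocks, interleaved or
not, via dendropy with underscores preserved); writing is conservative
(non-interleaved, symbols "01", missing "?", labels quoted only when
needed). A gap symbol "-" makes no sense for presence/absence data and is
mapped to missing with a warning.

A character is *uninformative* when its observed (non-missing) states are
constant — all 0, all 1, or nothing observed at all. Such characters carry
no grouping signal and are removed before analysis; the filter report
accounts for every input column and filtering is idempotent. Taxon removal
(`drop_taxa`) deliberately does **not** re-filter: the pipeline's documented
order is drop → filter, as two explicit steps.

## Distances and treelikeness

Distances are uncorrected proportions ("p-distances") with pairwise deletion:
d(i,j) = (# jointly observed characters that differ) / (# jointly observed).
This is the standard convention for 0/1 data in split-network software; no
evolutionary correction is applied. A pair with zero jointly observed
characters is an error, reported by name.

For each quartet the three pairwise-distance sums are sorted m₁ ≥ m₂ ≥ m₃.
The delta score is (m₁ − m₂)/(m₁ − m₃); the Q-residual is (m₁ − m₂)² after
dividing the whole matrix by its mean off-diagonal distance (so "mean
distance = 1" is the normalization convention — the Q-residual has no
universally fixed constant, and this choice is documented rather than
assumed compatible with every external implementation). Quartets with
m₁ = m₃ (all three sums equal, including the all-zero case) score 0 by
convention, avoiding 0/0. Per-taxon scores are means over the C(n−1,3)
quartets containing the taxon. Delta is invariant under relabeling and
global rescaling; Q-residual only under relabeling.

## NeighborNet

The circular ordering is built agglomeratively: clusters are paths whose two
endpoints stay "active"; cluster pairs are selected by the neighbor-joining
criterion Q(i,j) = d(i,j) − r(i) − r(j) on average-linkage cluster
distances, endpoints within the selected pair by the same criterion at node
level, and each merged 3-chain (x, y, z) is immediately reduced to two
combined nodes u, v with

    d(u,·) = ⅔ d(x,·) + ⅓ d(y,·),  d(v,·) = ⅓ d(y,·) + ⅔ d(z,·),
    d(u,v) = ⅓ (d(x,y) + d(x,z) + d(y,z)).

Ties break toward the lowest index pair, making the ordering deterministic.
The implementation is cross-checked in the test suite against the
independent R implementation in phangorn on tie-free random inputs.

Split weights are then fitted by non-negative least squares
(scipy's Lawson–Hanson active-set solver) over all n(n−1)/2 interval splits
of the ordering, with weights below 10⁻⁸ dropped — reproducible sparsity.
On additive (tree) distances this recovers exactly the tree's splits.

The splits graph is constructed as the planar dual of a chord arrangement:
taxa sit on a circle, each split becomes a chord separating its interval,
chords sharing an endpoint gap are perturbed by nesting depth so that two
chords cross iff their splits are incompatible. Faces of the arrangement
(computed with shapely's polygonizer) are the network's nodes; edges connect
faces across a chord and carry the split index with length = weight. A
compatible split system therefore yields a tree, and each incompatible pair
a box.

## Substitution model and likelihood

The two-state general reversible model has stationary frequencies
(π₀, π₁) and rate matrix normalized so one unit of branch length is one
expected substitution at stationarity (μ = 1/(2π₀π₁)); transition
probabilities are closed-form, P₀₁(t) = π₁(1 − e^{−μt}). Among-character
rate variation is discrete-gamma with 4 equal-probability categories
represented by category *means* (not medians): means are deterministic,
integrate exactly to 1, and — importantly — the simulator uses the identical
discretization, so parameter-recovery experiments compare like with like.

The likelihood is computed by postorder pruning with pattern compression;
missing cells contribute a flat partial (1, 1). Because analyzed matrices
normally have constant characters removed, the default ascertainment
correction ("variable") divides each character's likelihood by
1 − P(all 0) − P(all 1); "none" is available for raw simulation output.
Two implementations exist deliberately: a general children-list numpy path
(public `log_likelihood`, accepts multifurcating trees) and a compiled
binary-tree kernel (numba) used inside the sampler; a test pins them to each
other at 10⁻¹³, and the numpy path to brute-force state enumeration at
10⁻¹⁰. No log-space scaling is used in the pruning core: with ≤ ~60 tips and
two states, partial likelihoods stay far from double-precision underflow.

## MCMC

A single Metropolis–Hastings chain (no Metropolis coupling — at ≤ 40 taxa and
~100 binary characters a single chain mixes adequately, and the ESS
diagnostic guards quality). Priors:

- topology: uniform over rooted topologies satisfying the constraints;
- node ages: root height fixed at 1 (resolving the height/rate
  non-identifiability); each non-root internal age is a uniform fraction of
  its parent's age. This "cascade" prior is properly normalized for every
  topology (density ∏ 1/age(parent)), which keeps the topology marginal
  exactly uniform — verified by the data-free 4-taxon test, where the three
  unrooted topologies are sampled uniformly (χ² p > 0.01);
- clock rate ~ Gamma(2, 2); π₁ ~ Uniform(0,1); α ~ Exponential(1);
- relaxed clock: independent mean-1 lognormal branch-rate multipliers,
  log-sd σ ~ Exponential(3). This is an *uncorrelated* simplification of
  autocorrelated relaxed clocks: it captures rate heterogeneity across
  branches without modelling inheritance of rates, which would add
  complexity the package's comparisons do not require;
- non-clock: free branch lengths ~ Exponential(5).

Proposals: NNI (swap a child of an internal node with its sibling; age
violations and constraint-breaking proposals are rejected — constraint
enforcement is by rejection, i.e. prior mass zero outside the constrained
space), node-age slide uniform within (oldest child, parent), multiplicative
scales for clock rate/α/σ/branch lengths with Hastings factor, reflected
slide for π₁. An NNI changes the tip set of exactly one node, so constraint
checking is O(#constraints) using per-node bitmasks. An outgroup is
implemented as a monophyly constraint on its complement, which pins it to
the root in every sample.

Sampling starts at generation 0, so a run of G generations sampled every s
yields ⌊G/s⌋ + 1 trees; burn-in removes ⌊burnin_fraction × n_sampled⌋
(2,000,000 / 500 at 25% → 4001 sampled, 3001 retained). The ESS estimator
uses FFT autocovariances with Geyer's initial monotone positive-sequence
truncation, capped at n; a constant series reports n (degenerate).

## Marginal likelihoods and Bayes factors

Stepping-stone sampling uses the power ladder β_k = (k/K)^{1/0.4}
(quantiles of Beta(0.4, 1); K = 50 by default), traversed from the
posterior toward the prior with the chain state carried between rungs and
the first 25% of each rung's generations discarded. Each rung contributes
logSumExp((β_{k+1} − β_k)·logL) − log N, and runs are repeated (3 by
default) with consecutive seeds, averaging the per-run log marginal
likelihoods arithmetically. The combiner is generic over any power-posterior
sampler and is validated against the closed-form beta-binomial conjugate
marginal in the tests; at K = 1 it reduces to importance sampling from the
prior. The harmonic-mean estimator is provided for completeness, computed
stably by logSumExp, and always flagged as less reliable (its classic upward
bias is itself asserted in a test).

Log Bayes factors are differences of log marginal likelihoods, categorized
(natural-log units) as: < 1 "not worth more than a bare mention", 1–3
"substantial", 3–5 "strong", ≥ 5 "decisive". The two estimates must come
from the same method.

## Synthetic data

The generator mirrors the inference model: pure-birth (Yule) trees scaled to
root height 1; characters evolved under Mk2+Γ with the same 4-category mean
discretization; i.i.d. missingness. Defaults emulate the shape of a
40-language, ~100-feature typological dataset: π₁ = 0.35 (features more
often absent than present), α = 1 (substantial rate heterogeneity), 10%
missing cells. Borrowing — the non-treelike ingredient — is modelled as the
simplest contact event: at a uniform random time, a recipient lineage copies
the donor lineage's current state for one character, with a Poisson number
of events per character (mean `borrowing_rate`). Characters without events
are simulated in one vectorized pass; characters with events are replayed
chronologically in time slices.

What this emulates and what it does not: the simulator produces the
statistical signature the methods assume (clocklike signal plus horizontal
noise); it does **not** model dependencies between typological features,
areal geography, lineage extinction, or realistic borrowing asymmetries.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under its own assumptions, not fidelity of those assumptions to
real language change.

`make_scenario` builds the two competing dispersal topologies: a two-taxon
pair ("Yen_*") either sister to everything else (`early_split`, pair MRCA a
child of the root, attached at age 0.3) or grafted inside the first of two
subclades (`nested`). Tags in the tip labels let experiments score recovery.

## Scales used in tests and the acceptance script

Problem sizes were chosen so the full suite runs in a few minutes while
keeping each check statistically meaningful: scenario power experiments use
10 taxa × 2000 characters (the character count at which the generating
topology is reliably identified) with stepping stone at K = 10 and 1500
generations per rung; the constrained-clade and recovery checks use 12
taxa with 30,000-generation chains; the data-free uniformity check uses
100,000 generations. The headline model comparison is replicated across ten
simulated datasets and is expected to favor the generating (unconstrained)
model in at least nine.

## Known limitations

- The relaxed clock is uncorrelated; autocorrelated rate models are out of
  scope, and strict-vs-relaxed comparisons are reported but not treated as
  calibrated benchmarks.
- Constraint sets must be nested or disjoint (checked up front).
- The NeighborNet ordering, like all agglomerative implementations, is a
  heuristic: the exhaustive-ordering test guarantees optimality only at
  n = 5, and tie-breaking (lowest index pair) may differ from other
  implementations on exactly tied inputs.
- Marginal-likelihood values depend on the documented priors; comparisons
  across software are meaningful in sign and magnitude class, not to
  fractions of a log unit.
- Polymorphic or multistate (k > 2) characters and character weighting are
  unsupported.
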