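# dyphylo

Phylogenetic analysis of binary presence/absence character matrices — built
for typological (structural) linguistic data of the kind used to test
competing dispersal hypotheses for language families, but applicable to any
taxa × {0,1,?} matrix.

The package implements the complete two-track workflow:

1. **Distance/network track** — uncorrected p-distances with pairwise
   deletion of missing data; NeighborNet split networks (agglomerative
   circular ordering + non-negative least-squares split weights);
   treelikeness statistics. For every quartet {i,j,k,l} the three pairwise
   distance sums are sorted m₁ ≥ m₂ ≥ m₃, and

   - delta score δ = (m₁ − m₂)/(m₁ − m₃) ∈ [0, 1] (0 = perfectly additive),
   - Q-residual q = (m₁ − m₂)² after rescaling the matrix to mean distance 1,

   averaged over all C(n,4) quartets and per taxon.

2. **Bayesian track** — Metropolis–Hastings MCMC over strict-clock
   (optionally relaxed or non-clock) trees under the two-state reversible
   model with discrete-gamma rate variation (Mk2+Γ) and ascertainment
   correction for variable-characters-only matrices; monophyly/outgroup
   constraints; stepping-stone marginal likelihoods over a Beta(0.4, 1)
   power ladder, run in triplicate and averaged; Bayes factors
   log BF = log mₗ(A) − log mₗ(B); majority-rule consensus trees and
   consensus networks of posterior samples.

Constraining a group (e.g. "all non-Yeniseian languages form a clade")
encodes an "early split" hypothesis; comparing its marginal likelihood
against the unconstrained model asks whether the data support that
hypothesis — log BF ≥ 3 natural-log units is conventionally read as strong
evidence.

## Worked example

```python
import dyphylo as dp

# simulate a 10-language dataset whose true history nests the two-language
# "Yeniseian" pair inside one coastal subclade
cfg = dp.SimulationConfig(n_taxa=10, n_chars=2000, seed=42, missing_rate=0.1)
tree, matrix = dp.make_scenario("nested", cfg)

# network track
dm = dp.distance_matrix(matrix)
scores = dp.treelikeness(dm)
print(f"avg delta = {scores.avg_delta:.3f}, avg Q = {scores.avg_q_residual:.4f}")

# Bayesian track: does forcing the pair outside everything else hurt?
model = dp.SubstModel(pi1=0.35, alpha=1.0, ascertainment="none")
ingroup = frozenset(t for t in matrix.taxa if not t.startswith("Yen"))
base = dict(n_generations=0, sample_every=1, burnin_fraction=0.0)
unc = dp.stepping_stone_logml(matrix, model, dp.MCMCConfig(**base, seed=1),
                              K=10, per_step_generations=1500, n_runs=1)
con = dp.stepping_stone_logml(matrix, model,
                              dp.MCMCConfig(**base, seed=1,
                                            constraints=(dp.Constraint(ingroup),)),
                              K=10, per_step_generations=1500, n_runs=1)
bf = dp.bayes_factor(unc, con, "unconstrained", "constrained")
print(f"log BF = {bf.log_bf:.1f} [{bf.category}], favoring {bf.direction}")
```

Output:

```
avg delta = 0.230, avg Q = 0.0020
log BF = 86.3 [decisive], favoring unconstrained
```

The delta score is well above zero (finite data are never perfectly
additive) and the Bayes factor decisively rejects the early-split
constraint, recovering the truth of the simulation.

The same workflow runs from the shell:

```sh
dyphylo simulate --scenario nested --n-taxa 40 --n-chars 100 --seed 7 \
    --out sim.nex --tree-out sim.nwk
dyphylo matrix filter --in sim.nex --out filtered.nex --report filter.tsv
dyphylo nnet --in filtered.nex --out splits.nex --scores scores.tsv
dyphylo run --config analysis.json   # full pipeline, see AnalysisConfig
```

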