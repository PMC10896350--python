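# defenseflux

Do bacterial defense systems restrict horizontal gene transfer? `defenseflux`
implements a phylogenomic pipeline for asking that question at the level of
individual species trees: it reconstructs the ancestral presence of every
accessory gene family and every defense system on a rooted species tree,
converts the reconstructions into a per-branch **gene gain rate**, and tests
each defense system for association between its branch state and that rate.
Supporting analyses cover CRISPR spacer turnover (a proxy for CRISPR-Cas
activity), spacer-to-gene protospacer matching, phylogenetic co-occurrence
profiling, and genomic colocalization of defense systems with other gene
families. A ground-truth synthetic-data generator produces every input the
pipeline consumes, so the whole chain is testable against known answers.

It is aimed at microbial comparative genomicists who already have a rooted
core-genome tree, a gene presence/absence matrix (Panaroo-style Rtab) and a
defense-system table per genome, and want the branch-level gain/association
analysis without assembling a dozen external tools.

## The model and the statistic

**Gain–loss model.** Each binary trait (gene family or defense system)
evolves along the tree as a two-state continuous-time Markov chain with gain
rate *g* (0→1) and loss rate *l* (1→0), both per unit branch length. Over a
branch of length *t*,

    P01(t) = g/(g+l) · (1 − e^{−(g+l)t}),
    P10(t) = l/(g+l) · (1 − e^{−(g+l)t}).

One global (*g*, *l*) pair is shared by all trait columns of a matrix and
fitted by bounded maximum likelihood (Felsenstein pruning, root prior at the
stationary frequency g/(g+l) by default). Marginal posterior presence
probabilities p_v ∈ [0, 1] at every node come from the up–down algorithm.

**Branch statistics.** For the branch from parent *u* to child *v*:

    G_b = Σ_families max(0, p_v − p_u)        (raw gain; losses ignored)
    g_b = G_b / max(t_b, ε)                   (normalized gain rate)
    s_b = (p_u + p_v) / 2                     (defense branch state)

**Association test.** For each defense system, Spearman's ρ between g_b and
s_b across all 2n−2 branches, with a permutation null (shuffle one vector,
10,000 times, two-sided exceedance, pseudo-count p = (k+1)/(N+1)). A system
is called **negative** (gain-inhibiting) when ρ < −0.3 and p < 10⁻⁴,
**positive** when ρ > 0.3 and p < 10⁻⁴, otherwise **none**.

**Supporting statistics.** Fritz–Purvis D for phylogenetic signal in binary
traits (≈1 random, ≈0 Brownian-like) with the standard trait filters;
binomial observed-vs-expected co-occurrence with Bonferroni correction;
circular-genome colocalization against a sampled chromosomal null; and the
spacer turnover rate T = (1 + J)/(1 + d) for genome pairs at patristic
distance d < 1, where J is the Jaccard distance between spacer-cluster
repertoires.

## Worked example

Simulate a 100-genome species with two defense systems — DS1 suppresses the
accessory gene gain rate fivefold (multiplier 0.2), DS2 has no effect — then
run the inference chain:

```python
from defenseflux import (
    SimulationConfig, simulate_dataset, GainLossModel,
    GainDefenseAssociation, branch_gains, defense_branch_states,
)

cfg = SimulationConfig(n_tips=100, n_accessory_ogs=200, seed=42,
                       effect_multiplier=0.2)
ds = simulate_dataset(cfg)

og = GainLossModel(ds.tree, ds.matrix).fit()
print(og.summary())

defense = GainLossModel(ds.tree, ds.defense_table).fit()
flux = branch_gains(og.ancestral_probabilities(), ds.tree)
states = defense_branch_states(defense.ancestral_probabilities(), ds.tree)
res = GainDefenseAssociation(flux, states).fit(n_perm=10_000, seed=42)
print(res.summary())
```

Output:

```
Gain-loss model (two-state CTMC, shared rates)
==============================================
n tips:         100
n traits:       200
gain rate g:    0.253795
loss rate l:    1.00689
root prior pi:  0.201316
stationary g/(g+l): 0.201316
log-likelihood: -5511.17
converged:      True

Gene gain rate vs defense system state (Spearman, permutation null)
====================================================================
systems tested: 2   branches: 198
permutations:   10000   thresholds: |rho| > 0.3, p < 0.0001
calls: negative=1 positive=0 none=1

              rho  p_perm  n_branches      call
system_id
DS1       -0.5711  0.0001         198  negative
DS2        0.0644  0.3688         198      none
```

The inhibitory system is recovered as a strong negative association at the
permutation floor p = 1/10001 < 10⁻⁴; the neutral system is (correctly) not
called. The fitted gain rate 0.254 is the *effective* accessory gain rate
under partial suppression by DS1 (the unsuppressed base rate in the
simulation is 0.5).

The same run is available from the shell:

```sh
defenseflux run-all --config config.yaml --output-dir out/
```

where `config.yaml` holds a `simulation:` block (or paths to a Newick tree,
an Rtab matrix and a defense table), producing `association.tsv`,
`branch_flux.tsv`, ancestral-state TSVs, a run log and a provenance JSON.

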