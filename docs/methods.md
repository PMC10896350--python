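# Methods

## Overview

`defenseflux` asks whether carrying a defense system changes how fast a
bacterial lineage acquires accessory genes. The analysis runs entirely on a
rooted species tree with branch lengths in substitutions per site: gene
presence/absence is mapped backwards in time with a probabilistic gain–loss
model, gains are accumulated per branch, and each defense system's branch
state is correlated with the per-branch gain rate under a permutation null.
Everything downstream of tree building and annotation is in scope; tree
inference, orthology calling, defense-system detection and CRISPR array
detection are upstream tools whose outputs this package consumes.

## The gain–loss model

Each binary trait evolves independently along the tree as a two-state CTMC
with gain rate `g` and loss rate `l` (events per unit branch length). The
transition kernel is closed-form (no matrix exponentials needed), the trait
likelihood is computed by Felsenstein pruning with per-node rescaling of
partial likelihoods (stable beyond 400 tips), and node marginals come from
the up–down (inside–outside) pass. Tips are pinned to their observed 0/1
states in the output.

Assumptions worth stating plainly:

* **One shared rate pair per matrix.** All accessory gene families share a
  single (g, l); likewise all defense systems in a table. Real gene families
  differ in mobility, so the shared-rate model is deliberately the simplest
  one that yields per-node presence probabilities; per-column fitting is
  possible via the same API (fit on a one-column matrix) but is noisy.
* **Root prior = stationary frequency** g/(g+l) by default, overridable.
  This removes a free parameter and is exact for a trait at equilibrium.
* **Independence across columns** given the tree — no co-gain/co-loss
  modelling.

Fitting maximizes the summed log-likelihood over (log g, log l) with L-BFGS-B
in the box [1e−6, 1e3]², starting from a method-of-moments point (the matrix
mean fixes g/(g+l), total rate starts at 1). The likelihood surface is
smooth and unimodal in practice; the optimizer is deterministic from its
fixed start. An all-constant matrix raises a degeneracy error instead of
returning boundary estimates. On synthetic data (200 tips, 500 families,
g = 0.5, l = 1.0) the fit recovers both rates within a few percent.

## Branch statistics

For the branch from parent `u` to child `v` with length `t`:

* raw gain `G_b = Σ_families max(0, p_v − p_u)` — only positive increments in
  posterior presence count, so `G_b` is probability mass, not an integer
  event count, and is never rounded;
* normalized gain `g_b = G_b / max(t, ε)` with `ε = 1e−6` (config-exposed).
  Core-genome trees contain zero-length branches; the floor makes the
  division defined while leaving ordinary branches untouched. Whether
  near-zero branches should instead be excluded is a sensitivity question
  the flux API leaves open (pass a filtered tree);
* defense branch state `s_b = (p_u + p_v)/2`.

The root has no incoming branch and contributes nothing; a rooted binary
tree with n tips yields exactly 2n − 2 branch rows.

## The association test

Spearman's ρ between `g_b` and `s_b` over all branches, per defense system.
The null shuffles one vector uniformly (equivalent in distribution to
shuffling both), N = 10,000 times by default; the p-value is the two-sided
pseudo-count estimator (k+1)/(N+1), whose floor 1/10001 makes the p < 10⁻⁴
rule attainable exactly at N = 10,000. One-sided exceedance and the raw
k/N estimator are switches, not defaults. Calls use the dual threshold
(|ρ| > 0.3 and p < 10⁻⁴); no further multiple-testing correction is applied
across systems — the stringent dual threshold is the false-positive control.
Per-system generators are seeded as (master seed, column index), so results
are independent of execution order and safe to parallelize.

### Known miscalibration of the naive null

The package's own calibration experiments (see
`tests/test_acceptance.py::test_association_stage_calibration_under_null`,
which fails by design and is kept failing deliberately) show that the
shuffle null is **anticonservative at the stage level**: under a no-effect
simulation the rejection rate at α = 0.05 is ≈0.10–0.14 rather than 0.05.
The mechanism is precisely isolable with ground truth in hand: using *true*
per-branch gain counts and *true* defense branch states, ρ is exactly
calibrated (branch-local gain events are independent across branches, so one
side of the correlation is exchangeable and the permutation test is valid);
substituting either side with its ancestral-reconstruction estimate inflates
sd(ρ) by ~20–45%, because marginal posteriors smooth across neighbouring
branches (adjacent branches share a node's posterior) and neither vector
remains exchangeable. The dual-threshold call is much less affected — the
|ρ| > 0.3 requirement sits ~4 null standard deviations out even after
inflation, and the no-effect false-call rate measured over seeded replicates
is 0. Users should treat the permutation p-value as optimistic for
branch-level hypotheses and rely on the dual threshold; a phylogenetically
structured permutation scheme is out of scope by design and listed below as
a limitation.

## Comparative statistics

* **Mann–Whitney U** (two-sided) for genome-level count contrasts: exact
  enumeration when both groups are ≤ 20 without ties, otherwise the
  tie-corrected normal approximation with continuity correction.
* **Fritz–Purvis D** for a binary tip trait:
  `D = (S_obs − mean S_Brownian)/(mean S_random − mean S_Brownian)`, where S
  sums |change in nodal trait estimate| across branches and nodal estimates
  are bottom-up daughter means. The random null shuffles tip labels; the
  Brownian null thresholds simulated standard-Brownian tip values at the
  observed prevalence; both use 1,000 draws by default. Calibration on
  100-tip trees: mean D within 1 ± 0.15 (shuffled) and 0 ± 0.15 (Brownian).
  Trait filters are strict inequalities: gene families kept at D > −0.2,
  defense systems at D > 0.2.
* **Co-occurrence**: for a trait pair, observed count O of genomes carrying
  both versus the independence expectation E = n·f_a·f_b, one-sided binomial
  tail P(X ≥ O | n, f_a·f_b), Bonferroni over tested pairs; traits outside
  the 10–90% frequency window are excluded first. An accessory family counts
  as associated with a multi-gene system only if significant against every
  gene of that system.
* **Colocalization**: the statistic is the median over genomes of the
  minimum circular start-to-start distance (bp) between any system gene and
  any member of the family, chromosome only. The anchor choice
  (gene start, not midpoint) and the chromosome-only null pool are explicit
  decisions; plasmid genes never enter the null. The null redraws the
  statistic for gene families sampled uniformly from the chromosomal pool
  (families co-occurring with the system in ≥ 1 genome); p = (k+1)/(n+1)
  for null medians ≤ observed.

## CRISPR spacers

Spacers are clustered single-linkage across all genomes: two spacers link if
an ungapped local alignment on either strand covers ≥ 80% of *both*
sequences at ≥ 90% identity. The 80% mutual-overlap rule is the search
criterion the repertoire comparison is built on; the 90% identity cutoff is
this package's choice (the corresponding database-search criterion is an
e-value, which has no clean ungapped-scan equivalent) and is config-exposed.
Cluster IDs are deterministic (lexicographically smallest member sequence),
and clustering is invariant to input order.

Turnover for a genome pair at patristic distance d < 1 with Jaccard distance
J between cluster repertoires is the **ratio** T = (1+J)/(1+d) ∈ [0.5, 2).
The ratio reading is the one under which more active CRISPR-Cas (fast
acquisition and loss) scores higher — dissimilarity per unit divergence; the
product reading, which rewards divergence itself, is kept behind a flag for
sensitivity analysis. Jaccard is computed over clusters, not raw sequences;
on synthetic data the two coincide because simulated spacers are unique
random 32-mers.

Protospacer matching declares a hit when an ungapped alignment of the spacer
(either strand) to a gene covers ≥ 90% of the spacer at ≥ 95% identity. The
production scanner seeds on exact 12-mers and evaluates candidate diagonals;
at the default thresholds any qualifying window of a ≤ 60 nt spacer contains
an exact 12-mer run, so seeding is lossless. A naive sliding-window scanner
(exhaustive diagonals and windows, no shared scan code) serves as the
reference; the two agree exactly on randomized pairs including
reverse-complement and boundary plants.

## Synthetic data: what it emulates, and what it does not

The generator produces a full input bundle with ground truth: a Yule tree
scaled to root height 1 (clocklike, as core-genome trees approximately are);
defense systems evolving by the same gain–loss chain the inference assumes;
accessory families whose per-branch gain rate is `base · m^{s̄_b}` with
`s̄_b` the endpoint average of the *true* defense states — multiplicative so
that rates stay positive, m = 1 is exactly "no effect", and the simulated
estimand aligns with the inference-side `s_b` definition; spacer arrays with
Poisson acquisition and exponential loss of unique 32-mers; and circular
genome layouts in which defense genes sit inside fixed mobile-element island
windows with cargo families while background families are uniform.

Default conditions (chosen once as a realistic species-scale study): 200
genomes; two defense systems with gain = loss = 1 (stationary prevalence
0.5, inside the 20–80% analysis window); 400 accessory families with base
gain 0.5 and loss 1.0 (stationary prevalence 1/3); effect multiplier 0.2 on
the first system (strong inhibition) and 1.0 elsewhere; spacer acquisition
30 and loss 1 per unit branch length (≈30-spacer arrays); a 2 Mb chromosome
with 1 kb genes and one 20 kb island carrying the first system plus 10 cargo
families (islands are a small fraction of the genome, as in real layouts).
Every generator is byte-reproducible from (config, seed); seeds for
sub-generators are spawned from the master seed.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: rate heterogeneity across gene families,
co-transfer of genes in blocks (each family evolves independently), HGT
network structure, annotation error in presence/absence calls, non-clocklike
trees, unresolved polytomies, sequence-level evolution of spacers
(turnover ground truth is exact because spacers are unique k-mers), and
plasmid-borne defense systems.

## Numerical and design choices

* Preorder integer node IDs (root 0, parents before children) assigned
  deterministically at parse time; internal Newick labels are annotations,
  never identifiers. Zero-length branches are legal input. A root with > 2
  children is accepted with a log warning (pre-rooted trees are expected;
  rooting is upstream).
* Per-node rescaling of partial likelihoods prevents underflow on large
  trees; marginals are normalized per node.
* Permutation and Monte-Carlo p-values all use the (k+1)/(N+1) form to avoid
  reporting zero.
* Prevalence windows are closed intervals: defense systems kept at
  prevalence in [0.20, 0.80] (with a species gate of ≥ 2 retained systems),
  core families at ≥ 0.95, profiling window [0.10, 0.90]. Boundary cases are
  tested explicitly.
* ANI dereplication is single-linkage at ≥ 99.9% (auto-detecting 0–1 vs
  0–100 scales), representative = lexicographically smallest ID;
  conflicting asymmetric entries are an input error, applied before the
  prevalence filters.
* Pipeline reports contain no timestamps; reruns from the same config and
  master seed are byte-identical. Provenance JSON records the config hash,
  seed and package version.
* Test problem sizes (e.g. 500 null datasets at 100 tips × 100 families for
  calibration; 20 seeds at 200 × 400 for effect recovery; 50 replicates for
  D calibration) are the package's chosen desk-scale study conditions: large
  enough for the binomial/calibration bands asserted, small enough to run
  routinely.

## Limitations

* The permutation null ignores phylogenetic autocorrelation of branch
  statistics; see the calibration section above. No branch-aware null is
  provided.
* The shared-rate gain–loss model is a simplification; mixture or
  gamma-rate models are out of scope, as is stochastic mapping of event
  counts.
* Colocalization distances are start-to-start on the chromosome; ICE or
  prophage boundary detection, and plasmid nulls, are not modelled.
* The spacer-clustering identity threshold stands in for a database-search
  e-value; conclusions sensitive to that cutoff should vary it via config.
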