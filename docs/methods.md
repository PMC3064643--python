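# Methods

`asexpop` models an *asexual complex*: a sexual ancestor species together
with the assemblage of clonal lineages repeatedly derived from it, all
competing in one arena for drift and selection.  The scientific question
the toolkit addresses is whether clones merely turn over neutrally (new
clones replace old ones by drift, the way neutral alleles do under
mutation–drift balance) or additionally *decay* — lose fitness as a
function of age, e.g. through Muller's ratchet — and whether the two
regimes can be told apart from sequence data.

## Genealogy model

Both simulators emit the same object: a rooted binary tree over sampled
individuals, tips at time 0, time measured in generations before present.
Every branch carries two durations, its total span and the number of
generations its lineage spent inside an (unfounded) clone.  The root is
the most recent common ancestor and is always a sexual individual; where
a multi-way merger is forced (all of a clone's lineages collapsing into
its founder; several founder lineages meeting the star-shaped sexual root
of the forward model) it is represented as a chain of zero-length binary
branches.  Serialization is standard newick with total length as the
branch length and the asexual duration in a bracketed `[&asex=...]` tag,
children canonically ordered by smallest descendant tip label.

## Forward (individual-based) simulator

A haploid clonal population of `N` individuals in `d` demes of `N/d` on a
finite linear stepping-stone.  Per generation, in a fixed order:
Wright–Fisher reproduction within demes with fitness `(1-s)^k` for an
individual carrying `k` deleterious mutations; migration as a symmetric
binomial exchange across each adjacent deme pair (deme sizes stay
constant; the terminal demes have one neighbour); clone recruitment as
`Poisson(c)` founders replacing uniform residents of deme 1, each founder
mutation-free by default (`founder_load="equilibrium"` instead draws
`k ~ Poisson(U/s)`, the deterministic mutation–selection balance of a
sexual population); finally `Poisson(U)` new mutations per individual.
The order — a founder is censused before it mutates — is a documented
constant.  At the end `z` tips per deme are sampled and their pedigree
traced; a lineage that reaches a founder event attaches to the single
sexual star root, with the stem above the founding sexual (asexual time
zero).  All initial individuals count as founders, so every lineage
terminates at the root.

Neutral-locus variation is produced by overlaying mutations on the
recorded pedigree (fixed count or per-generation rate), not by explicit
forward neutral mutations; both overlay modes are available.

## Backward (coalescent) simulator

`d_C` sexual demes (finite island model, backward migration probability
`m_C` per lineage per generation) plus `L_C` clones whose sizes partition
`N_C` by a broken-stick draw (uniform breakpoints, largest-remainder
rounding; the draw is conditioned on every clone holding at least `z_C`
individuals so the sample is drawable).  Within an unfounded clone each
lineage pair coalesces with probability `1/size` per generation.  Looking
backward, a clone is founded — all its remaining lineages merge into one
sexual founder placed in a uniformly chosen sexual deme — with
per-generation hazard `P'` (neutral turnover) or `1-(1-f')^a'` where `a'`
is the candidate age in generations (decay).  The decay founding time
therefore obeys `P(T>t) = (1-f')^(t(t+1)/2)` exactly, which the tests use
as an analytic oracle (mean ≈ 3.91 generations at `f'=0.1`).  Sexual
lineages migrate and coalesce within demes (`1/deme_size` per pair per
generation) until the grand MRCA.

The discrete-generation process is simulated event-to-event with
geometric waiting times, which is exact for the per-event hazards because
they are constant between state changes; whenever the per-generation
probability that *something* happens exceeds 0.2 the simulator steps
generation by generation instead, so small demes are handled without
approximation.  Simultaneous events within one generation are applied
sequentially at the same time stamp (zero-length branches).  A hard cap
of `10^3 x N_sex` generations guards against non-termination.

## Mutation overlay

Infinite-sites placement: `S` mutations are assigned to branches
multinomially with weights equal to total branch length ("total" dataset)
or asexual-only length ("pruned" dataset); `overlay_rate` draws
per-branch Poisson counts instead.  Branches subtending the entire
sample are excluded (a mutation there would be fixed, not segregating).
Each mutation marks a fresh 0/1 column, so outputs are perfect
phylogenies and a four-gamete check always passes.

## Neutrality statistics

Per-dataset (not per-site) mean pairwise differences Θ_π, Watterson's
Θ_S = S/a1, Tajima's D, Fu & Li's D* (the no-outgroup version with the
corrected variance constants; η = S under infinite sites), the
theoretical minimum D_min (D with π replaced by its all-singleton value
2S/n), and the scaled ratio D/|D_min|, which keeps the sign of D and
equals −1 exactly at the singleton extreme.  S = 0 makes D and D*
undefined and raises, never returns 0; D additionally requires n ≥ 4
because its variance constants vanish identically at n = 3.  Empirical
null bounds come from standard single-population coalescent simulations
conditioned on (n, S) — 1000 replicates by default — with two-tailed
empirical p-values.

Calibration note: with S fixed, D* is a function of the singleton count
alone and hence coarsely discrete (21 atoms at S = 20).  Its tail atoms
carry 1–3% mass, so the inclusive coverage of empirical 2.5%/97.5%
bounds can only jump across the nominal 95% (0.927 → 0.977 at n = 10,
S = 20).  Coverage is therefore assessed with the standard mid-p
convention for discrete statistics: values tied with a bound count half.
Under that convention both D and D* cover within [0.93, 0.97].

## Alignment pruning

Two procedures isolate post-formational polymorphism from an aligned
FASTA of sexual and asexual individuals:

* **site pruning** deletes every column segregating among the sexual
  sequences, then the sexual rows.  It can only miss inherited variants
  whose sexual carriers were not sampled, and can only over-prune sites
  that mutated independently in sexuals and asexuals — both quantified
  on simulated truth in the tests.
* **tree pruning** optimises the reproduction-mode character on a rooted
  haplotype tree under asymmetric parsimony (sex→asex costs one step,
  the reverse is forbidden; the unique optimum labels a node asexual
  exactly when all tips below it are asexual), maps site changes onto
  branches by Fitch optimisation with a deterministic downward pass
  (ambiguities resolved toward the alphabetically first base — one
  canonical optimum among equally parsimonious placements), and retains
  mutations on branches leading to asexual nodes.  Retained mutations
  are binarised into a matrix over asexual individuals; mutations fixed
  among them (e.g. the stem of a single monophyletic clade) carry no
  frequency information and are dropped.

Columns containing gaps or N are excluded from all segregating-site
counts (conservative choice).  A small maximum-parsimony search supports
datasets without a published tree: exhaustive over unrooted topologies up
to 9 haplotypes (enumeration beyond that is computationally out of reach
— 2 027 025 topologies at 10 tips and growing double-factorially),
random-order stepwise addition with leaf re-insertion hill climbing and
10 restarts above; an externally supplied newick tree is preferred when
available.  Ties break to the canonical smallest topology.  The 4X rule
flags a cluster pair as distinct species when mean between-cluster
per-site divergence exceeds four times the larger within-cluster per-site
Θ_π ("sequence difference" is taken per site); singleton clusters are
skipped with a warning.

## Comparative analysis

The trait table assembles, per complex, the neutrality indices of total
and pruned datasets plus candidate predictors.  Each predictor enters a
Gaussian linear model `E(y) = b0 + b1 X`; models are compared by AICc
(`-2logL + 2K + 2K(K+1)/(n-K-1)`, with K = 3 for slope models, 2 for the
null) and by evidence ratios `exp(dAICc/2)`.  Conventions chosen to
reproduce the published analysis: the Gaussian log-likelihood uses the ML
variance RSS/n (not REML); the null model is fitted on every row with a
defined response while each slope model uses its own complete cases, with
AICc computed at that n.  Because AICc values are not comparable across
models fitted to different rows, the *ranking* uses each model's evidence
ratio against a null refitted on its own rows; this equals the AICc
ordering whenever the models share n.  Published age intervals enter as
midpoints and ages are converted to generations (Mya × 10^6 ×
generations/year, natural log).  Ages reported only as "LGM" (Last
Glacial Maximum) default to 0.05 Mya: that value back-solves the
published model-1 fits exactly (both R² and slope to printed precision
for both pruning methods), and the fits' sensitivity across 0.01–0.05
Mya is below 0.05 in R².  The packaged transcription's boolean and proxy
columns (vertebrate, isolation, ploidy) are best-effort reconstructions
where the published table is not explicit; its latitude and
sexual-sample-size columns are unavailable and the corresponding models
are skipped.  The allopatric/sympatric age comparison is a one-sided
pooled-variance t test.

## Clonal-age distribution fitting

The empirical cumulative curve of lineage ages (log10 axis, proportion
i/n at sorted ages, duplicates collapsed) is fit by least squares with
three families: a straight line in log10(age) (uniform-on-log density, 2
parameters), a Gaussian CDF in log10(age) (2), and a k-term
"multi-diffonential" mixture (3k−1 free parameters: per term two rates
b > a > 0 — parameterised as log a and log(b−a) — and softmax weights
summing to one), where one diffonential term has density
`f(x) = ab/(b−a) (e^{−ax} − e^{−bx})`, i.e. the law of a sum of two
exponentials.  The mixture is optimised from 20 seeded random starts;
non-convergence is flagged, never silent.  AIC uses the Gaussian-residual
form `n ln(rss/n) + 2p`.  Residual-sign runs tests operationalise
"systematically distributed residuals"; note they are descriptive, not
calibrated — residuals of any cumulative-curve fit are bridge-
autocorrelated even under the true family, so only relative comparisons
between families are meaningful.

## Synthetic complexes

`generate_complex_fixture` closes the loop between the simulators and the
empirical pipeline: a coalescent genealogy with sexual samples, standing
sexual polymorphism overlaid with weights equal to each branch's *sexual*
portion and post-formational sites with the asexual portion, everything
encoded as nucleotides on a random ancestral sequence at distinct
positions (derived base uniform over the three alternatives; no
transition/transversion structure, consistent with infinite sites), plus
a truth table labelling every variable column's phase.  What the
generator does *not* emulate — recurrent mutation, rate heterogeneity,
gaps, misalignment, unsampled sexual diversity — bounds what passing
pruning tests say about real alignments: they certify the logic, not
robustness to alignment artefacts.

## Problem sizes and determinism

Default study conditions follow the simulation settings above
(`N_C = 25 000`, 10 clones, 2 sexual demes, 5 samples per deme/clone,
1000 replicates); the test suite and examples run the same pipelines at
reduced sizes chosen as the package's own desk-scale conventions
(e.g. `N_C = 2 500` with 500 replicates for the decay-direction
experiment; 2000 replicates for the forward coalescent-equivalence
check).  All stochastic entry points take a `numpy.random.Generator` or
a seed; equal seeds give byte-identical outputs.

## Known limitations

No diploidy, recombination, back-mutation, beneficial mutations or
epistasis in the forward model; no gene flow from asexuals back to
sexuals anywhere (mode changes are strictly sex → asex); no
model-based tree inference (parsimony only) and no bootstrap supports;
the comparative layer fits single-predictor models only.  Tajima's D is
undefined below four samples, and both D and D* are conservative for
unpolarized (folded) empirical input, where singletons are counted on
the minor allele.
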