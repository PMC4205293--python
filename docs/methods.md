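# Methods

`refugia` reconstructs the demographic history of a wide-ranged savanna
tree from two lines of evidence: the genetic diversity of modern
populations, and the distribution dynamics implied by ensembles of
hindcast climatic-suitability maps. This note documents the models, the
numerical choices, and what the synthetic data can and cannot show.

## The structured serial coalescent

Gene genealogies for each microsatellite locus are simulated backward in
time for samples spread over `D` demes (default `D = 20`, with the study's
per-population diploid sample sizes, 414 individuals in total). The state
of the process is the set of ancestral lineages and the deme each one
currently occupies.

* **Coalescence.** Within a deme holding `k` lineages of current diploid
  size `N(t)`, each pair coalesces at rate `1/(2N(t))`, so the total deme
  rate is `k(k-1)/(4N(t))`. Because every deme follows the same size
  trajectory, the per-deme rates are pooled into a single inhomogeneous
  clock and the deme of the event is then drawn proportionally to its pair
  count.
* **Size trajectories.** `N(t)` is anchored at three epochs: the present
  (`t = 0`), 500 generations ago and 1,750 generations ago — under the
  12-year generation time these correspond to the mid-Holocene (6 ka) and
  the Last Glacial Maximum (21 ka). Between anchors the size follows an
  exponential curve `N(t) = N(ta) * (N(tb)/N(ta))^((t-ta)/(tb-ta))` and is
  constant beyond the last anchor. Waiting times under the exponential
  size are drawn by inverting the integrated hazard in closed form within
  each epoch (no time discretisation); an `interpolation="instantaneous"`
  mode holds the older anchor value within each epoch instead, since
  serial-coalescent simulators differ in this convention.
* **Migration.** Under the `sink` rule every lineage outside deme 1 moves
  to deme 1 at 0.01 per generation (all present demes descend from deme
  1); under the `island` rule every lineage moves to a uniformly chosen
  other deme with the same total rate. Rates are constant between events,
  so migration competes with coalescence through ordinary exponential
  clocks.
* **Fusion and termination.** The Retraction hypothesis pools all
  surviving lineages into deme 1 at the 1,750-generation anchor (the
  forward-time reading: peripheral demes appear after the LGM from a
  single source that had shrunk). Every scenario additionally fuses at a
  deep cap (default 50,000 generations) so a single root is guaranteed;
  a hard time cap turns a structurally impossible configuration (no
  migration, no fusion) into an explicit error rather than a hang.

### The six demographic hypotheses

All demes start at `N0 = 10,000` diploids; anchors are per deme.

| Hypothesis            | N0     | N500   | N1750  | Migration | Notes |
|-----------------------|--------|--------|--------|-----------|-------|
| Stability 21–0 ka     | 10,000 | 10,000 | 10,000 | sink      | constant |
| Retraction 21–6 ka    | 10,000 | 10,000 | 50,000 | sink      | fusion at 1,750 |
| Expansion 21–0 ka     | 10,000 | 5,179  | 1,000  | sink      | single decline; N500 lies on the curve |
| Expansion 21–6 ka     | 10,000 | 10,000 | 1,000  | sink      | decline only before 6 ka |
| Expansion 6–0 ka      | 10,000 | 1,000  | 10,000 | sink      | mid-Holocene bottleneck |
| Multiple Refugia 21–0 | 10,000 | 5,179  | 1,000  | island    | finite island model |

Backward growth toward a smaller `N1750` means expansion forward in time.
Scenarios with a large ancestral size (Retraction, Stability) retain more
deep coalescent diversity; the simulated mean heterozygosity ranks
Retraction > Stability > Expansion variants, which is what makes the
model comparison informative.

## Mutation model

Microsatellites follow the strict stepwise mutation model: each branch
receives a Poisson number of mutations with mean `mu * length`
(`mu = 0.01` per allele per generation, the highest rate reported for
plant microsatellites, chosen because allele-size information contributes
to differentiation here), each mutation shifts the repeat count by one
step up or down with equal probability, and sizes are floored at one
repeat. The ancestral state defaults to 100 repeats so the floor is
effectively never reached. At mutation–drift equilibrium this model gives
gene diversity `He = 1 - 1/sqrt(1 + 2*theta)` with `theta = 4*N*mu`; the
simulator is validated against this closed form at `theta` of 4, 40 and
400, and its genealogies against an independent coalescent implementation
(msprime) for constant-size panmictic cases.

## Summary statistics

Per population: mean alleles per locus (A), rarefied allelic richness
(Ar), observed heterozygosity (Ho), Nei's unbiased gene diversity (He),
and the within-population inbreeding coefficient f. Across populations:
Weir–Cockerham FIS/FST/FIT from per-allele variance components summed
over alleles and loci, and Slatkin's RST from allele-size variances
(within- vs total mean squared pair difference, combined across loci as a
ratio of sums, which is more stable than averaging per-locus ratios).
Permutation tests randomise the unit appropriate to each null: whole
individuals among populations for FST, gene copies within populations for
FIS, and allele-size assignments within loci for the FST = RST contrast.

Numerical conventions worth stating:

* The rarefaction base for Ar is `g = 4` gene copies ("two individuals"
  read as two diploids); `g = 2` is available since rarefaction software
  conventions differ and reported Ar values for such data are often
  surprisingly low.
* Missing genotypes are dropped per locus and population, never imputed.
* Allele frequencies are count-weighted across unequal sample sizes.
* Linearised FST (`FST/(1-FST)`) keeps non-positive entries as-is; a
  value of exactly 1 maps to an infinity sentinel.

## Closed-form demographic conversions

MCMC genealogy samplers are out of scope; `theta` is instead obtained
by inverting the SMM equilibrium relation (`theta = ((1/(1-He))^2 - 1)/2`). Conversions:
`Ne = theta/(4*mu)`; expected TMRCA `= theta/mu` generations (the
large-sample limit `4*Ne`), times 12 years per generation;
`Nem = M*theta/4`. With the study-wide `theta = 7.033` these reproduce a
TMRCA of 8.44 ka; note the corresponding `Ne` is 175.8, whereas the
study-wide `Ne` of 2,109 reported alongside that theta is not consistent
with `theta = 4*mu*Ne` at `mu = 0.01` — both values are surfaced, neither
is forced to agree. The growth
convention `theta_t = theta_now * exp(-g*t)` (backward `t`, positive `g`
meaning a smaller past) is the default, with a flag for the opposite
convention, because published descriptions use both.

## Model selection

Each candidate hypothesis gets a reference distribution of `R` replicate
simulated mean-He values (`R = 2000` at full scale). Relative support RS
is the proportion of simulated values strictly above the observed one
(ties count as not higher); the two-tailed probability is
`P = 2*min(RS, 1-RS)`. The relative likelihood is the height of the
smoothed reference density at the observed value divided by the maximum
height — a ratio, not a literal product, since only a ratio is bounded by
one and vanishes for out-of-support observations. Density estimation uses
a Gaussian kernel with Silverman's bandwidth; a fixed-bin histogram mode
exists for sensitivity analysis. `AIC = -2 ln L` with the parameter-count
term treated as equal across hypotheses (no per-model counts exist), so
Akaike weights are `exp(-0.5*dAIC)` normalised over the estimable models.
A hypothesis whose RS is exactly 0 or 1 is flagged inestimable and
reported with RS only.

Under this simulator the Expansion 6–0 ka reference distribution centres
near mean He of 0.95 rather than at the observed 0.893: with migration
pooling lineages into deme 1 and regrowth to 10,000 beyond the
mid-Holocene bottleneck, roughly 90% of lineage pairs coalesce in the
large ancestral phase. Self-consistency is therefore tested the way a
simulation study can: data generated under a hypothesis must return a
median RS near one half and the top Akaike weight for that hypothesis.

## Suitability-ensemble post-processing

Stacks are full factorials of 13 algorithms x 4 AOGCMs x 3 periods
(52 layers per period) with per-(algorithm, AOGCM) TSS weights.

* **Consensus**: cell-wise TSS-weighted mean per period; negative weights
  are floored at zero so below-chance models cannot invert the ensemble.
* **Range size and dynamics**: cells with suitability >= 0.3 (the
  threshold comparison is inclusive); for each (algorithm, AOGCM) pair
  and period pair, `diff = older - recent` cells is classified as
  Stability within ±199 cells, Retraction above, Expansion below.
* **Refugium**: cells suitable in all three periods.
* **Uncertainty partition**: per-cell hierarchical ANOVA with AOGCM and
  algorithm nested in time and crossed within periods; type-I sums of
  squares on the balanced design (where they are unambiguous); overall
  proportions are component sums over cells over the total.
* **Association tests**: Pearson chi-square and likelihood-ratio G2 on
  classification contingency tables (a saturated log-linear model is not identifiable at these degrees of
  freedom, so only association tests are provided).
* **Centroids**: unweighted means of suitable-cell centres (a
  suitability-weighted mode exists); distances to populations are
  great-circle kilometres.

## Spatial genetics

Isolation by distance is tested with a Mantel correlation between
linearised FST and log great-circle distance, with significance from
simultaneous row/column permutations (default 10,000; two-sided on |r|).
Diversity–climate relationships use linear quantile regression at
`tau = {0.1, 0.5, 0.9}` (quantile-level conventions vary across
studies; these defaults bracket the envelope). A "triangular envelope" is flagged
when the upper-quantile slope is significant while the lower is not or
has the opposite sign — maximum diversity responds to the predictor while
minimum diversity does not.

## Synthetic data

The genotype generator wraps the coalescent simulator under a chosen
truth scenario and then forms diploids with an inbreeding parameter F
(default 0.21): with probability F, per individual and locus, the second
gene copy duplicates the first. This reproduces the observed
within-population fixation without modelling the mating system, and the
estimated f recovers F in expectation.

The map generator plants a Gaussian high-suitability region whose width
changes between periods according to the requested dynamic (radii scale
0.625/1.0/1.5 of a base width of one tenth of the grid edge, enough to
clear the ±199-cell band by a wide margin on the default 80 x 80 grid)
plus Gaussian effects for time, AOGCM(time), algorithm(time) and noise.
Component variances are obtained by solving the linear system that makes
the *expected* hierarchical-ANOVA sums of squares match the requested
proportional fractions, with effects i.i.d. across cells and levels; the
total latent scale (default SD 0.08 per cell) keeps clipping to [0, 1]
rare, so recovered proportions stay within a few thousandths of the
planted ones. What the synthetic stack does not emulate: spatial
autocorrelation of model errors, coastlines/masks, correlated algorithm
families, and any real climate signal — passing tests show the
post-processing arithmetic is right, not that real ensembles behave this
way.

Synthetic coordinates are uniform draws in a savanna-like lon/lat box;
the study's population coordinates are not published numerically, so
these are placeholders, not reconstructions.

## Problem sizes used in the checked runs

The packaged checks run scaled-down versions of the full analysis: 100 to
500 replicates for reference distributions (2,000 at full scale), 60
replicates and 5 demes for the self-consistency experiment, 60 x 60 to
80 x 80 grids for map stacks, and 99 to 4,999 permutations for the
randomisation tests. All sizes are arguments, so full-scale runs only
change configuration values.

## Known limitations

* Serial-coalescent simulation packages differ in epoch-growth
  interpolation and serial-sampling details; both interpolation
  conventions are implemented, and the exponential one is the default.
* The moment estimator of theta ignores the sampling variance structure a
  genealogy sampler would capture; credibility intervals are out of scope.
* Quantile-regression slope p-values use the estimator's asymptotic
  covariance, adequate at n = 18-20 populations only as a screening
  device.
* RST combines loci as a ratio of summed mean squares; per-locus values
  are available where the averaging convention matters.
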