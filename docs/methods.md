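# Methods

## The question being simulated

A breeder running a conventional self-pollinating-crop programme wants to
release variety *combinations* for a binary cereal-legume intercrop (IC)
without rebuilding the programme. The minimal adaptation is to keep the
usual monocrop (MC) pipeline — crossing, line fixation, then preliminary
(PYT), advanced (AYT) and elite (EYT) yield trials — and, at some stage,
start phenotyping faba-bean x triticale combinations instead of pure
stands. Switching early maximizes direct selection on IC performance but,
because combinations scale quadratically, slashes the number of lines that
fit the trial budget; switching late tests many more lines but relies on
indirect selection through the MC-IC genetic correlation R. The package
quantifies this trade-off by stochastic simulation of two line-development
methods (doubled haploids, DH, and ear/pod-to-row, EPR) crossed with three
switch stages, three heritabilities and three values of R.

## Genome and founder model

Each crop is collapsed to a single diploid chromosome (1.1 Gbp
faba-bean-like, 0.99 Gbp triticale-like) with a genetic map of 1 Morgan
carrying 2000 segregating sites. Both map length and site count are
configuration, not biology: recombination operates on the Morgan scale and
1 Morgan per chromosome is the usual single-chromosome convention; 2000
sites keep the 1000 QTL a proper subset. Founders are 100 fully homozygous
lines, produced by one of two generators:

* **coalescent** (default for scenario runs): msprime neutral coalescent
  with recombination on a uniform map over the physical length (scaled to
  the genetic length), effective population size 1000, binary mutations
  thinned to exactly 2000 polymorphic sites; each sampled haploid genome
  is doubled into a homozygous founder. This carries realistic linkage
  disequilibrium and a rare-allele-rich site-frequency spectrum.
* **beta**: per-site allele frequencies from the U-shaped Beta(0.5, 0.5)
  spectrum, independent across sites (no LD), monomorphic columns redrawn.

The choice matters: with rare-allele-rich founders, aggressive early
bottlenecks (28 lines entering an IC-first PYT) permanently lose more
favourable alleles, so the founder model shifts the balance between early
and late switching; the beta generator, whose variants are common and
unlinked, is gentler on early bottlenecks. Absolute convergence times and
asymptote heights carry founder-model signature in either case; the
effective population size of the coalescent history is a free parameter
chosen once (1000) rather than fitted.

## Trait model

MC and IC performance are additive traits controlled by the same 1000 QTL
(sampled uniformly from the segregating sites). Effect pairs are drawn from
a bivariate standard normal with correlation R; the IC effect vector is
then re-mixed with the MC effects (Gram-Schmidt in founder GV space) so the
*realized* founder genetic correlation equals R exactly — with 100 founders
the realized correlation of merely-sampled effects scatters around R with a
standard error near 0.1, which would blur the R = 0.3 / 0.5 study contrast.
Effects are affinely rescaled so founder genetic values (GVs) have mean 0
and variance 1 per trait; all outputs are on this founder-sd scale, which
is what makes the 0.005 convergence threshold meaningful.

The GV of an IC combination is the arithmetic mean of its components' IC
GVs, g = (g_f + g_t)/2. Phenotypes add one normal deviate with entry-mean
variance sigma_e^2 / r, where sigma_e^2 = (1 - h^2) sigma_a^2 / h^2,
sigma_a^2 = 1 is the *founder* additive variance (the noise level is not
re-estimated as variance depletes — h^2 is a design property of the trial
system, defined against founder variability), and r is the number of plot
replications. Replication is simulated as entry-mean noise rather than r
plot records; for truncation selection on entry means the two are
statistically identical. An IC combination is one phenotyped entity with
one noise draw — the two crops in a plot are not given independent errors,
matching the view of the mixture plot as the experimental unit.

## Mendelian machinery

Meiosis uses the Haldane model: crossover counts Poisson(map length),
positions uniform, no interference, no obligate crossover, random starting
haplotype. This is analytically checkable (recombinant fraction
(1 - e^(-2d))/2), and the test suite verifies it against those closed
forms. Crossing, selfing and DH doubling are built from independent
gametes; DH lines are exactly homozygous by construction. Populations are
dense int8 arrays and the gamete and GV inner loops are numba-compiled —
the scenario grid needs tens of millions of gametes.

## Breeding schemes

Every cycle starts from 14 crosses per crop; cycle 1 parents are 14
founders sampled per crop, later cycles recycle trial entrants (see below).
Each cross yields one S0 plant.

* **DH**: each S0 yields doubled-haploid lines directly, without
  selection: 28 per S0 in MC scenarios (392 PYT entries per crop), 2 per
  S0 when IC testing starts at the PYT (28 entries per crop).
* **EPR**: each S0 is selfed into a family nursery and advanced S1 to S4
  under within-family visual selection on the MC trait at h^2 = 0.1
  (single-plant scores, noise at r = 1), keeping the top 8% each
  generation and refilling the nursery by selfing; at S4 the same 8% rule
  advances the PYT entrants. The nursery is sized to the advancement
  target — 350 plants per family when 28 advance (MC scenarios, 392
  total), 25 when 2 advance (IC-start PYT, 28 total) — so the visual
  selection intensity is identical across scenario variants; an intensity
  that instead varied with the switch stage would confound the comparison
  of switch stages with pre-trial selection pressure. The visual trait is
  the MC trait: IC partners do not exist before the PYT.

Trial budgets are fixed across all variants: PYT 784 single-rep plots, AYT
144 entries x 2 reps, EYT 36 entries x 4 reps. MC stages phenotype lines
per crop and truncation-select per crop; IC stages phenotype the full
factorial of combinations (28x28 = 784, 12x12 = 144, 6x6 = 36) and score a
line by the mean phenotype over all its combinations — an empirical general
mixing ability; the selection count at each stage is whatever the next
stage's mode requires (e.g. an MC PYT advances 12 lines per crop when the
AYT is IC, 72 when it is MC). The EYT is always IC — genetic progress is
defined on the 36 elite combinations — and selects nothing within the
cycle. Ties are broken by stable entry order, so runs are bit-reproducible.

A caveat on the mixing-ability score: averaging a line's phenotype over 28
partners divides the entry-mean noise variance by 28, so IC-first
selection at the PYT is nearly noise-free even for low-heritability
traits. An alternative rule (`ic_selection="combination"`) instead walks
combination plots best-first and keeps the lines appearing in them, which
is noisier and concentrates selection on fewer families; it is provided
because the two rules bracket how strongly early IC testing can rank
candidates, and the relative merit of an early switch depends on it.

Parents for the next cycle are the 6 + 6 lines that enter the EYT. This
keeps the recycled pool identical in size across switch stages, so scheme
variants differ only in *which* six lines they identify, not in how much
diversity they happen to carry forward; recycling instead from the AYT
entrants (72 per crop after an MC PYT, 12 after an IC PYT) is available as
a configuration switch, but its stage-dependent pool size confounds the
switch-stage comparison with diversity retention. The 14 new crosses are
random distinct-parent pairs, repeats allowed (C(6,2) = 15 pairs exist).
No variance-preserving mating design is applied, deliberately: gain
saturating as genetic variance depletes is part of the studied behaviour.

## Measurement, convergence, summaries

Per cycle the simulator records the mean and variance (ddof = 1) of the
true IC GVs of the 36 EYT combinations. Scenario output is per-replicate
trajectories; summaries use the replicate-averaged trajectory.
Convergence is the first cycle whose absolute increment falls below 0.005
(first-hit rule; re-divergence afterwards is ignored), reported on the
replicate-averaged trajectory. The grid summary reports the asymptote
(final-cycle replicate mean), the convergence cycle and an early gain rate
(mean per-cycle gain over the first five cycles).

## Problem sizes and numerical choices

The full study grid (54 scenarios x 100 replicates x 20 cycles) is hours of
compute; the package's own analysis and the acceptance script use a
comparison set of 13 scenarios at one representative heritability
(h^2 = 0.5) with 20 replicates x 15 cycles, where the qualitative orderings
between switch stages and methods are already stable. Unit tests use
further-reduced genomes (a few hundred sites); the engine by default
carries only the QTL columns through the breeding machinery, which is
exactly equivalent for every recorded quantity because meiosis depends only
on map positions and non-QTL sites never feed selection or measurement.

Replicate RNG streams derive from (base seed, replicate index) via
`numpy.random.SeedSequence`, making results invariant to replicate
execution order and worker count. Each replicate resimulates founders,
maps and effects, so replicate scatter includes founder-history
uncertainty; because the seed does not encode the scenario, scenarios run
under the same base seed share those founder histories replicate-by-
replicate (common random numbers), and scheme contrasts are paired on the
founder history rather than blurred by it.

## Known limitations

Purely additive traits (no dominance, epistasis or
genotype-by-environment interaction); a single location and season per
stage; no producer/associate decomposition of mixture performance; no
tester-based mixing-ability schemes, genomic selection, land-equivalent
ratio metrics, or cost accounting. Absolute GV units are founder standard
deviations of a synthetic founder panel; only orderings and qualitative
shapes — not absolute gains — should be read as predictions for real
programmes.
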