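# Methods

`straysink` estimates how strongly hatchery-origin salmon have genetically
introgressed into wild spawning populations, from three allele-frequency
snapshots per stream: a hatchery ("source") sample, a historical
("pre-hatchery") sample, and a contemporary sample taken roughly six
generations later. Because the historical DNA comes from archived fish
scales, much of it is cross-contaminated with DNA from other fish, so the
estimator is wrapped in a quality-control pipeline that includes a Bayesian
two-fish-mixture detector.

## The source-sink model of introgression

Each wild stream is treated as a sink receiving, every generation, a
fraction *m* of its gene pool from a source population whose allele
frequencies *Q<sub>l</sub>* are constant. The sink frequency at locus *l*
follows

    q_{t+1,l} = (1 - m) q_{t,l} + m Q_l,

with closed form after *n* generations

    q_{n,l} = (1-m)^n q_{0,l} + [1 - (1-m)^n] Q_l.

Two consequences drive everything downstream:

* **Geometric gap decay.** |Q − q_n| = (1−m)^n |Q − q_0| at every locus.
* **Slope diagnostic.** Regressing (Q − q_n) on (Q − q_0) through the
  origin across loci gives slope (1−m)^n exactly on noiseless input:
  slope 1 without introgression, < 1 with it. The regression has no
  intercept because the model relation has none.

The cumulative source-derived fraction after *n* generations is
1 − (1−m)^n.

**Assumptions.** Random mating (Hardy-Weinberg proportions) within every
collection; linkage equilibrium across loci (enforced by the LD screen);
constant source frequencies; constant *m*; no genetic drift in the sink.
Drift is deliberately absent from the likelihood; the generator offers an
optional Wright-Fisher resampling layer (`drift_ne`) purely for robustness
experiments, off by default.

### Likelihood and priors

Genotype counts in the three collections are multinomial under HWE at
*Q<sub>l</sub>*, *q<sub>0,l</sub>*, and the forecast
*q<sub>n</sub>(q<sub>0,l</sub>, Q<sub>l</sub>, m)*; the contemporary
frequency is never a free parameter. Priors: Beta(1/2, 1/2) on every
frequency (the equal-weight Dirichlet used in Bayesian assignment methods)
and a Normal(0, 1000) prior on *m* truncated to [0, 1], which is flat for
all practical purposes. A logit-scale variant
(`m_prior="logit-normal"`) is available; it piles prior mass near 0 and 1
and is not the default.

### Sampler

Metropolis-within-Gibbs. Frequencies update with per-locus reflected
Gaussian random walks (loci are conditionally independent given *m*, so
all loci update in parallel); *m* updates with a scalar reflected random
walk against the summed contemporary likelihood. Proposal scales adapt
toward ~35% acceptance with a diminishing Robbins-Monro step during
burn-in and are frozen afterwards, so the post-burn-in kernel is a valid
fixed Metropolis kernel. Two chains start from dispersed *m* (0.01 and
0.5); the default run length is 100,000 iterations with 50,000 burn-in,
though 20,000/10,000 is ample at the default design and is what the
calibration studies use. Convergence is declared when the split-chain
potential scale reduction on *m* is ≤ 1.05; a credible interval wider
than 0.5 (posterior nearly as wide as the prior) is flagged
`weak-identification`, which happens when historical and source
frequencies barely differ.

Under HWE the multinomial genotype likelihood reduces, up to constants,
to a binomial in allele counts; the sampler exploits this for speed. The
estimate is invariant to global allele relabeling, and
(1 − posterior mean)^n agrees with the slope diagnostic on noiseless
input (both are tested).

## The two-fish contamination model

DNA extracted from an archived scale may be a pool of exactly two fish
from the same collection. Pooling four alleles and scoring a diploid
call, homozygotes are observed only when all four alleles agree, so the
apparent-genotype law at frequency *p* is

| apparent call | single fish | two-fish mixture |
|---|---|---|
| AA | p² | p⁴ |
| Aa | 2p(1−p) | 1 − p⁴ − (1−p)⁴ |
| aa | (1−p)² | (1−p)⁴ |

Each individual carries one Bernoulli(1/2)-prior indicator selecting the
model at **all** loci jointly — contamination is a property of the
extract, not of a locus. With equal prior weight the posterior mean of
the indicator is the posterior probability of contamination, and the
exclusion rule "posterior > 0.75" is identical to "Bayes factor > 3".
The threshold is strict (exactly 0.75 is retained).

The Gibbs sampler alternates exact full conditionals: the indicator is
Bernoulli with success probability L_con/(L_con + L_unc), and each locus
frequency is conjugate Beta given latent allele counts — clean fish
contribute their two alleles, contaminated apparent homozygotes
contribute four copies, and contaminated apparent heterozygotes
contribute a latent reference-allele count c ∈ {1,2,3} drawn
∝ C(4,c) p^c (1−p)^{4−c}. Allele frequencies are therefore re-estimated
jointly with the indicators rather than fixed from a clean subset. One
chain starts all-contaminated, the other all-clean; split-chain R-hat on
each locus frequency and on the mean indicator must be ≤ 1.05. A panel
that is monomorphic in the observed data carries no information and
returns posteriors of exactly 0.5 with status `uninformative`.

At the archival design (100 fish × 100 informative loci, 30–50%
contamination) the classifier's measured sensitivity is ~100% with ~0%
false positives; its false-positive rate decreases with panel size
(tested at 25/50/100 loci).

## Quality-control pipeline

Stage order: otolith-marked strays and individuals missing > 20% of loci
are removed (strictly greater — a fish at exactly the threshold is
kept); the microsatellite screen flags extracts showing ≥ 3 alleles at
any multi-allelic locus; loci typed in fewer than 55 fish in *any*
historical collection (applied per collection, the stricter reading) or
monomorphic across all collections pooled are dropped; the Bayesian
contamination screen excludes flagged fish; then the HWE and LD locus
screens run on the cleaned collections.

* **HWE exact test.** Full conditional enumeration over heterozygote
  counts given the allele counts, two-sided by probability ordering
  (outcomes no more probable than the observed one). Exact enumeration
  replaces Markov-chain approximation — for biallelic loci it is both
  exact and fast, and it is verified against an exact-fraction oracle
  for every table with ≤ 10 individuals.
* **Multiple testing.** Holm's sequential procedure at α = 0.01 across
  loci within each collection; a locus is removed only if it stays
  significant in strictly more than half of the collections.
* **LD screen.** A permutation test of the log-likelihood-ratio G on the
  3×3 genotype table replaces Markov-chain exact tests; its null
  p-values are verified uniform. A monomorphic partner makes the
  statistic constant, so p = 1 (keeping the majority rule well defined).
  A pair is "linked" when significant at 0.05 in more than half of the
  collections or when listed as known-linked. Chains are broken first by
  removing the locus with the most linked partners; simple pairs lose
  the lower-heterozygosity locus, ties broken by the larger historical
  missing fraction, then by name.
* **Replicate concordance.** Re-genotyped subsets report the fraction of
  doubly-scored genotypes that disagree; half of the discordance is
  attributed to each pass.

Every filter is idempotent and the per-collection accounting identity
(initial = removed + retained) is enforced.

## Population summaries

Reference-allele frequencies by direct counting; observed heterozygosity
as the heterozygote fraction among typed fish; expected heterozygosity
with Nei's small-sample correction 2p(1−p)·2n/(2n−1). Pairwise F_ST is
Weir–Cockerham θ with per-locus variance components combined as a ratio
of sums across loci (the estimator both standard implementations reduce
to for two populations); negative estimates are reported as computed.
It is verified against an independent nested-ANOVA derivation.
Differentiation uses Fisher's exact test on the 2×2 allele-count table
per locus, combined across loci by Fisher's method. Exact conditional
tests are discrete and therefore conservative: under the null the
combined p-value is stochastically **larger** than uniform (measured
median ~0.75 at n = 50). The calibration tests assert the property that
actually holds — empirical size never exceeding the nominal level — not
uniformity. Hierarchical (three-level) AMOVA is out of scope; the
pairwise machinery supports the temporal comparisons the introgression
stage needs.

## Synthetic-study generator

The generator emulates the study design: one hatchery source (200 fish)
and four sink streams, each with a historical archival collection (140
fish initially; ~50% of extracts two-fish contaminated, so ~60–70
survive screening, matching the real study's post-QC range) and a
contemporary collection (500 fish with a 1% otolith-marked stray
fraction). Defaults: 135 biallelic loci with base frequencies
Uniform(0.05, 0.95) (keeps loci informative, avoids boundary
degeneracies), per-generation rates (0.257, 0.066, 0.060, 0.011)
spanning the estimated range, n = 6 generations, 5% uniform missingness,
and a 7-locus, 10-allele equifrequent microsatellite panel. Contamination
donors are drawn uniformly from the other fish of the same collection;
strays are pure source fish (they are removed before analysis, so no
hybrid strays are modelled). Sink propagation is deterministic, matching
the estimator's likelihood.

What the generator does **not** emulate: genetic drift (unless
`drift_ne` is set), linked loci, genotyping error beyond missingness,
hybrid or multi-fish mixtures, cross-collection contamination, and
locus-specific amplification failure. Passing recovery tests therefore
show the estimator is correct and calibrated *under its own model
assumptions*; they do not bound the bias drift or model misspecification
would add on real data.

## Numerical choices and sizing

* Frequencies are kept in [1e-9, 1 − 1e-9] inside samplers; the
  Beta(1/2, 1/2) prior density is evaluated up to constants.
* The HWE test includes probability ties up to a relative jitter of
  1e-9 so enumeration matches exact rational arithmetic.
* Permutation p-values use the (1 + #{G* ≥ G}) / (B + 1) estimator.
* Seeds: every stage folds a stable CRC-based tag into the single run
  seed, so a run is bit-reproducible from its config and any stage can
  be replayed in isolation.
* Calibration studies use 12–24 replicates per condition at
  20,000-iteration chains; the full default pipeline uses
  10,000-iteration contamination chains. These sizes give Monte Carlo
  error well below the decision thresholds they feed.

## Known limitations

* No drift in the likelihood: for small sinks, drift inflates |Q − q_n|
  fluctuations and the estimator will absorb some of it into *m*.
* Frequentist coverage of the 95% credible interval at fixed *m* is
  slightly below nominal at large *m* (measured ~92% at m = 0.26),
  where the forecast compresses the information about *m*, and degrades
  for rates within a posterior-width of the boundary (the recovery
  calibration measures ~75% at m = 0.011), where the truncated
  posterior is skewed.
* With truth at the boundary (m = 0) an equal-tailed interval cannot
  cover it; use the posterior mean (≤ 0.02 under the null design).
* The binary mixture model ignores ≥ 3-fish pools and unequal DNA
  proportions; both push apparent genotypes toward heterozygosity, so
  in practice they are flagged, not missed.
* Historical samples are treated as pure pre-introgression snapshots
  even though their collection years may partially overlap early
  hatchery operation.
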