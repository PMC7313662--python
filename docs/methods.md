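# Methods

## The problem and the model

Classical genome scans flag windows whose summary statistics reject a
neutral Kingman-coalescent expectation. `mmcscan` instead treats sweep
detection as *model choice*: a hard selective sweep distorts the local
genealogy into a multiple-merger shape (many lineages coalescing nearly
simultaneously into the sweeping haplotype), which is exactly the genealogy
class produced by sweepstakes reproduction. The scan therefore asks, window
by window, whether the data are better fit by

* the **Kingman model** — neutral Wright–Fisher (WF) reproduction, or
* the **MMC model** — the ψ-coalescent of Eldon & Wakeley, in which a single
  diploid parent occasionally contributes a fraction ψ of the entire next
  generation,

and calls a window "sweep-like" when the rejection-ABC posterior probability
of the MMC model exceeds the 99th percentile of that probability under
matched neutral simulations. Neutral demography (bottlenecks) rescales
branch lengths but does not create multiple mergers, which is what gives the
approach traction against demographic confounding; very severe bottlenecks,
whose short internal branches mimic multiple mergers once mutations become
unlikely on them, remain indistinguishable — by either this approach or any
polymorphism-based method.

## Forward engine

Diploid WF populations of size N are simulated forward in time as a dense
2N × S derived-allele matrix managed by numba kernels.

* **Reproduction.** Each of the 2N child haplotype slots draws a parent
  haplotype uniformly (neutral), by fitness weighting 1 : 1+hs : 1+s on the
  beneficial genotype (sweeps), or — during a ψ episode — the first
  round(2Nψ) slots draw gametes from one uniformly chosen carrier of the
  focal marker m2, the rest from the whole population.
* **Recombination.** Per transmitted gamete, a Poisson(ρ·(L−1)) number of
  crossovers at uniform breakpoints, alternating parental strands.
* **Mutation.** Poisson(μ·L) new derived alleles per gamete at uniform
  discrete positions; a draw colliding with an active site is re-drawn
  (infinite-sites on discrete coordinates). The ancestral state is known by
  construction, so the unfolded statistics (Fu & Li) are exact.
* **Burn-in.** Every scenario starts from a monomorphic population and runs
  10·N neutral generations before anything else happens.
* **Bottlenecks.** Instantaneous down-sampling to round(βN) diploids
  (floored at 2 — the desk profile's β=0.2% at N=500 would otherwise round
  to a single diploid, which cannot reproduce bi-parentally) for
  0.005×4N generations, then instantaneous recovery by one reproduction
  event back to N.
* **Conditioning.** Sweeps and ψ episodes restart from the saved pre-episode
  state whenever the focal allele is lost (cap: 10,000 restarts), so
  retained replicates are conditioned on fixation.
* **Timing.** The beneficial mutation (or the ψ episode's m2) arises at the
  instant of bottleneck recovery. Sweep replicates are sampled at fixation.
  Neutral replicates are sampled τ ~ U[0, tau_max] generations after
  recovery; MMC replicates at m2 fixation with probability 1/21, otherwise
  at τ ~ U[0, tau_max] after fixation (one uniformly chosen epoch out of
  "fixation plus 20 random later time points").

`tau_max` defaults to N generations, approximating the fixation time of the
weakest sweep considered (2Ns=100), so neutral and selected replicates share
the same distribution of post-event sampling times.

All randomness flows from one seed through a SeedSequence: the kernels use
an explicit xorshift128+ stream, python-level draws a numpy Generator, so
identical seeds give bit-identical haplotype matrices.

An implementation note that cost a prototype afternoon: with a
double-buffered genotype matrix, compaction of fixed/lost columns must zero
the freed tail columns in *both* buffers, otherwise stale columns re-enter
as phantom variants when the site count grows back across a word boundary.
The engine's neutral behaviour is validated against Watterson's expectation
and against msprime (two-sample KS on S and π at matched 4NμL, 4NρL).

## Summary statistics

Eleven statistics per window, computed on the sampled haplotype matrix with
sites monomorphic in the window removed; π and S are per window, not per
site: S, π (mean pairwise differences), Tajima's D, Fu & Li's D and F
(unfolded, derived singletons), haplotype diversity n/(n−1)(1−Σf²), Wall's
B and Q (congruent adjacent bipartitions), Rozas' ZA and ZZ, and Kelly's
ZnS (r² on derived alleles). Statistics undefined on a window (all of them
at S=0 except S, π, haplotype diversity; the LD trio and B at S<2) are NaN
plus a degeneracy flag. Everything is validated to 1e-10 against
brute-force pair/bipartition enumeration in the test suite; no trusted
unfolded Fu & Li implementation is installed here, so its oracle is an
independent re-derivation of the 1993 constants plus the neutral
Monte-Carlo calibration (mean ≈ 0).

## ABC model choice

Training data are 10-kb regions (equal to the scan window, so training and
observed windows are exchangeable under the null) simulated per demography:
n Kingman + n MMC replicates, ψ ~ U[0.004, 0.08]. Preprocessing, fitted on
the pooled training matrix and reused for every target window:

1. **Degeneracy imputation.** NaN entries are replaced by the most extreme
   observed training value per statistic — the *minimum*, since
   zero-variation windows sit in the low-diversity tail (S=0, π=0) and the
   absence of variation is itself an MMC hallmark that must remain
   classifiable.
2. **Correlation pruning.** Greedy, in the fixed statistic order S, π,
   Tajima's D, Fu & Li's D, Fu & Li's F, haplotype diversity, Wall's B,
   Wall's Q, ZA, ZZ, ZnS: a statistic is dropped when its |Pearson r| with
   any already-kept statistic exceeds 0.8 (estimated on non-degenerate
   rows; constant columns dropped).
3. **Standardisation.** Centre/scale by training mean and SD.

A target window's posterior P(MMC) is the MMC fraction among the
round(0.10·R) nearest training rows in Euclidean distance (ties at the
boundary all included). Leave-one-out cross-validation classifies held-out
training rows (argmax posterior, exact ties counted as misclassified) over
a 1000-fold uniform subsample. The neutral threshold is the nearest-rank
99th percentile of P(MMC) over windows of neutral chromosomes simulated
under the same demography (windows pooled across positions and replicates).

The posterior is discrete (a fraction out of the accepted count) and has
point masses at its extremes: all zero-variation windows share one imputed
vector and hence one posterior value. A nearest-rank 99th percentile
estimated from too few windows can therefore land inside the top atom,
which with the strict ``p_mmc > threshold`` calling rule collapses the
call rate to zero. The pipeline default uses 20 neutral chromosomes; the
acceptance checks estimate the percentile from 110 chromosomes
(equilibrium calibration), 40 per bottleneck demography, and the
reproduction script from 60, which keeps the order statistic outside the
atom under the desk conditions.

## Scan and power evaluation

Observed chromosomes are scanned in sliding windows (desk scale: 10 kb
window, 5 kb step; full scale: 100 kb / 50 kb). A sweep replicate counts as
detected when at least one window whose span contains the sweep position
(at most two at default overlap) is called sweep-like; FPR is reported
per window over matched neutral replicates.

## Desk-scale study conditions

Full-scale conditions (N_e=10⁴ with λ=2 rescaling to N=5000, μ=2.4e-8,
ρ=2e-8, 5-Mb chromosomes, 30,000+30,000 training replicates) are far beyond
a workstation test run. The default desk profile preserves the quantities
the method is sensitive to while shrinking everything else:

| quantity | full scale | desk scale | preserved |
|---|---|---|---|
| N (diploids) | 5000 | 500 | 2Ns ∈ {100, 250, 500}, β ∈ {10%, 2%, 0.2%} |
| training region / window | 100 kb | 10 kb | region-mean segregating sites ≈ 14 |
| observed chromosome | 5 Mb | 100 kb | windows linked and (partially) unlinked |
| μ per site | 2.4e-8 | 1e-7 | ρ/μ = 1/1.2 |
| ψ prior | U[0.004, 0.08] | U[0.004, 0.08] | kept fixed, as under λ-rescaling |
| training replicates | 30,000/model | 2,000/model | — |
| sample size | unstated | 20 haplotypes | — |

The desk μ was chosen so training regions have mean population-wide S ≈ 14
(SD ≈ 10), matching the regime in which the ψ prior's upper bound was
justified (high ψ frequently yields zero variation). The ψ prior is kept at
its printed bounds rather than rescaled with N: the λ-rescaling convention
leaves ψ untouched, and that choice reproduces the qualitative regime of the
method (models discernable; MMC the harder model to classify, i.e. higher
leave-one-out misclassification). A 2Nψ²-preserving rescale was evaluated
and rejected during design because it inverts that ordering.

One desk-scale caveat: with the ρ/μ ratio preserved, a 100-kb desk
chromosome is *more* tightly linked than a 5-Mb full-scale chromosome, so
strong sweeps depress variation over most of the region rather than a
sharply localised valley. Detection (a called window overlapping the sweep
site) and the power orderings are unaffected; the spatial decay of P(MMC)
along the chromosome is compressed.

## What the generator does and does not emulate

Training and observed data come from the same forward engine, so passing
tests demonstrate internal consistency of the method (calibration of the
neutral threshold, separability of the models, power orderings), not
robustness on real data: no missing genotypes or phasing error, no
mutation/recombination rate heterogeneity, no background selection, known
ancestral states, and a single panmictic population apart from the ψ
mechanism.

## Numerical and degenerate-input choices

* Nearest-rank percentile for the neutral threshold (conventions differ;
  with 100 values 0.00..0.99 the 99% threshold is 0.98).
* Rejection ties at the acceptance boundary are all included; LOO posterior
  ties count as misclassification.
* r² is clipped to [0, 1] against float roundoff; columns identical or
  complementary count as the same bipartition for Wall's statistics.
* A beneficial mutation whose fixed position collides with a segregating
  neutral site is nudged one base (probability ~S/L per replicate).
* Dominance h = 0.5 (genic selection) by default.
* `segsites: 0` ms blocks carry no haplotype rows; such windows produce the
  canonical degenerate vector regardless of sample size.

## The ψ→0 limit

With round(2Nψ) = 0 the sweepstakes reproduction *operator* is exactly
standard WF reproduction, and the test suite verifies distributional
equality of (S, π) between ψ-mode and WF-mode epochs. The full MMC
*scenario* at ψ→0 is not Kingman, however: the episode still conditions on
the fixation of the neutral marker m2 and samples at or shortly after that
fixation — a "neutral sweep" that measurably depresses diversity (at
N=200: mean S 2.1 vs 2.9 against the Kingman scenario). This is a property
of conditioning on any fixation, not of ψ, and it vanishes from the
training distribution as ψ grows (the episode then ends in tens of
generations rather than ~4N).

## Desk-scale compression of the misclassification asymmetry

At full scale the MMC model is the harder of the two to classify (lower
TPR / higher FPR than the Kingman). At desk scale both leave-one-out
misclassification rates sit near 0.26–0.28 and their ordering is not
reproducible across training seeds (exact all-fold LOO, four seeds:
MMC−Kingman ∈ [−0.021, +0.025], mean ≈ 0). Two desk-scale effects nearly
cancel the asymmetry: zero-variation windows — frequent under high ψ —
share one imputed statistic vector and are classified reliably as MMC
(lowering MMC error), while the occasional zero-variation neutral window
joins the same cluster and is almost surely misclassified (raising Kingman
error). The corresponding acceptance test asserts the full-scale ordering and is
therefore expected to be marginal at desk scale.

## Known limitations

* Rejection ABC only; no regression adjustment, no ψ posterior estimation.
* The desk-scale power numbers are 50-replicate (tests) or 20-replicate
  (acceptance script) binomial proportions; orderings are asserted with a
  0.1 Monte-Carlo allowance.
* The infinite-sites collision re-draw ignores previously fixed positions,
  so re-mutation at an anciently fixed site is possible (rate ~μ²).
* The engine targets the scenarios of this method; it is not a general
  forward simulator (no gene conversion, selfing, or structured
  populations beyond the ψ mechanism).
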