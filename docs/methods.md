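# Methods

`linscr` estimates the density, abundance and sex ratio of a population
whose movements are confined to a branched, effectively one-dimensional
habitat network (a river system), from non-invasive genetic detections at
fixed sampling sites (latrines), and pairs those demographic estimates
with site-fidelity and population-genetic summaries.  This note records
the models, conventions and numerical choices, and what the synthetic
data do and do not emulate.

## Spatial capture–recapture on a linear network

**State space.** The habitat is a set of polyline edges joined at shared
vertices; all distances are arc lengths along the network, computed by
shortest paths through the vertex graph (scipy Dijkstra) with a direct
within-edge shortcut.  Cross-component distances are `+inf`, which gives
exactly zero detection hazard.  The state space discretizes every edge of
length L into `max(1, floor(L/spacing))` equal cells (points at cell
midpoints), so summed cell lengths equal the network length for any
spacing; cells are between one and two spacings long on short-remainder
edges.  Default spacing is 100 m for study-scale analyses.  The state
space is restricted to points within `4 sigma` (along the network) of any
detector, which retains essentially all activity-center mass under a
half-normal kernel; a pilot fit of the null model on the unbuffered space
supplies the sigma.

**Detection model.** Latrines are count detectors: individual i with
activity center s produces Poisson counts at detector k on occasion o
with rate

    mu(i,k,o) = effort[k,o] * lambda0 * exp(-d(s,k)^2 / (2 sigma^2)),

the hazard half-normal function.  Effort enters multiplicatively (binary
usage is effort in {0,1}).  `lambda0` may carry a sex effect, a
detector-specific behavioral response `bk`, or both (additive or
interactive); `sigma` may carry a sex effect.  `bk` is a persistent
once-triggered state: the rate at detector k changes from the occasion
after the individual's first detection at k, and the realized detection
sequence defines the state.

**Sex mixture.** Sex is a two-class finite mixture with proportion `psi`
of males.  Known-sex individuals enter as degenerate class memberships
(their likelihood term keeps the `psi_class` factor, so `psi` is informed
by the observed sex split as well as by detection differences); unknowns
are marginalized over both classes.  The mixture parameter is included
whenever any sex information is present, which makes the null detection
model a 4-parameter model on sexed data.

**Likelihood.** The full (unconditional) likelihood of an inhomogeneous
Poisson point process of activity centers with intensity D(s) (animals/km)
on the discretized network:

    -logL = Lambda - sum_i log( sum_c psi_c 1{sex_i ~ c}
                                sum_s D(s) cell(s) prod_{k,o} Pois(n_iko | mu) )
    Lambda = sum_s D(s) cell(s) sum_c psi_c [1 - exp(-sum_{k,o} mu_naive)]

with the naive (never-detected) bk state inside `Lambda`.  The complete
Poisson log-pmf (including `log n!`) is kept so deviances are comparable
across observed and simulated data.  Per-individual spatial sums are
accumulated in log space; the heavy inner products reduce to two
(individuals x detectors) by (detectors x points) matrix products per
mixture class, which keeps a full evaluation under a millisecond at the
default problem size.  The implementation is verified against an
independently coded loop-based marginalization (agreement < 1e-8 on
instances covering the mixture, bk x sex and covariate-density cases).

**Density models.** log D(s) is constant, or linear in the z-scored
latitude, or in the z-scored along-network distance to the release site
(the release covariate is a network distance, not Euclidean — the
covariate of interest is how far an animal must travel from the release
point).  Covariates are standardized over the retained state space.

**Estimation.** All positive parameters are estimated on the log scale,
the mixture proportion on the logit scale, by L-BFGS-B from three starting
points (one data-driven, two jittered with SD 0.25; seeds explicit).
The starting heuristic uses detected count per network length for D, the
half mean distance between an individual's detectors for sigma, and a
crude encounter-rate ratio for lambda0.  The covariance is the inverse of
a central-difference numerical Hessian (relative step 1e-4); a singular or
non-positive-diagonal result flags the fit as unusable for model
averaging, mirroring the exclusion of non-converged models from candidate
sets.

**Derived quantities and intervals.** N = sum_s D(s) cell(s); reported
density is N divided by total retained network length, which equals D
itself under the homogeneous model.  SEs of derived quantities come from
the delta method.  CIs for positive parameters are Wald intervals on the
log scale computed from the real-scale SE via
`se_log = sqrt(log(1 + (se/est)^2))`, yielding the familiar asymmetric
intervals (e.g. 83 with CI 47–144); the mixture proportion uses the logit
scale.  Model averaging over the competing set (AICc within 2 of the
best) uses Akaike weights and unconditional variances
`sum_m w_m (var_m + (est_m - mean)^2)`; a parameter absent from some
competing models (e.g. the post-detection lambda0 in models without bk)
is averaged over the models that define it and flagged.  AICc uses the
number of detected individuals as the effective sample size
(`AICc = AIC + 2K(K+1)/(n-K-1)`).

**Goodness of fit.** Parametric bootstrap: simulate a population from the
fitted density surface on the same state space, simulate detections from
the fitted detection model (sequentially over occasions so bk states
update from realized detections), refit the same model starting from the
MLE, and record W = deviance / (n_detected - K) with
deviance = -2 logL.  The p-value is the fraction of replicates with
W >= W_observed.  Under the generating model the p-values are
approximately uniform (over 20 seeded meta-replicates none fall below
0.05); strong unmodeled heterogeneity lowers them.

**Growth.** Average annual exponential growth over t years is
`lambda = (Nt/N0)^(1/t)`; its CI applies the same transform to the
abundance CI bounds, treating the founder count N0 as known.

## Genotype pipeline

**Consensus.** A locus is called heterozygous A/B when exactly two
alleles each appear in >= 2 replicates; homozygous A/A when A is the only
allele ever observed and appears in >= 3 replicates; otherwise missing.
The homozygote rule is strict: a single spurious allele anywhere among the
replicates blocks the call.  One measurable consequence (visible in the
simulations) is that false alleles at truly homozygous loci censor
exactly the loci they pollute out of the consensus, so the downstream
first-two-replicate false-allele estimate understates the generating rate
at those loci; the dropout estimate is unaffected.

**Sexing.** The Y marker amplifies only in males.  Two or more positive
replicates confirm a male; exactly one gives an unconfirmed male; zero
positives with >= 8 typed autosomal loci (enough template to make
repeated Y dropout implausible) gives a female, otherwise unknown.
Unconfirmed males are coded male downstream by default.

**Identity and matching.** The probability that full siblings share a
multilocus genotype, `PIsibs = prod_l (0.25 + 0.5 S2 + 0.5 S2^2 -
0.25 S4)`, with cutoff 0.01, sets the minimum locus count (8 here).
Samples typed at >= 8 loci merge into an individual when identical at
>= 8 shared typed loci and — under the conservative rule — any remaining
mismatch is dropout-consistent (heterozygote vs matching homozygote); the
lenient rule splits on any mismatch, so conservative counts are never
larger than lenient counts while total detections are identical under
both.  Matching closes transitively (union-find); a closure that chains
two members with non-dropout-consistent disagreement at >= 2 loci is
flagged, not silently merged, and within an individual a heterozygous
call overrides dropout-consistent homozygotes.  Conflicting sex calls
within an individual resolve to male, since a confirmed Y amplification
is stronger evidence than its absence.

**Error rates.** From the first two replicates of samples with full
(>= 8 locus) consensus: dropout is the fraction of amplified replicates
at heterozygous consensus loci showing a single allele; false-allele is
the fraction of amplified replicates containing an allele absent from the
consensus pair.  Zero denominators report the rate as missing, not zero.

**Subsampling.** The seeded field-subsampling selector splits duplicate
samples per scat, randomizes within latrine x occasion, keeps 3–4, and
falls back to the duplicate when a primary fails; with few enough samples
it is a no-op.

## Site fidelity

Per individual-latrine pair: permanence IT = (last - first capture
occasion)/(occasions - 1) and periodicity It = (capture occasions - 1) /
(last - first); SSFI is their harmonic mean, defined as 0 when either
component is 0 (hence for single captures).  The occurrence share IO is
computed and reported but does not enter the composite, which follows the
printed two-component formula.  Time is measured in survey occasions —
the occasions are the data's clock even when their calendar durations
vary — and the occasion-based reading of IT/It is an interpretation,
isolated in one function and switchable if a different clock is wanted.
Sex-specific means carry 95% percentile bootstrap CIs over individuals.
The sex contrast in latrine use is a Poisson regression (statsmodels GLM)
of distinct latrines per individual on a male indicator; for this binary
design the IRR equals the ratio of sex means, which the tests check
against an independent Newton solver.

## Population genetics

Observed heterozygosity is the fraction of typed individuals
heterozygous; expected heterozygosity uses Nei's unbiased correction
`2n/(2n-1) (1 - sum p^2)` by default (the plug-in value is also
computed).  Rarefied allelic richness is the hypergeometric expectation
`sum_a [1 - C(N-N_a, g)/C(N, g)]` with g defaulting to the smallest typed
copy count across populations per locus.  The inbreeding coefficient f
and differentiation theta are Weir–Cockerham variance-components
estimators, summed over alleles and loci before the ratio; f uses the
single-population reduction of the components.  CIs are percentile
bootstraps over loci (1,000 resamples).  Genotypes missing at a locus are
excluded locus-wise.  HWE and linkage-disequilibrium exact tests,
bottleneck tests, and effective-size estimation are out of scope; printed
summary values from external tools can still be compared via
`percent_decline`.

## Synthetic data

The generator produces every input the pipeline consumes, as a pure
function of (config, seed): a connected tree of constant-step sinuous
branches whose arc length is exact by construction; activity centers from
a homogeneous (length-inversion) or inhomogeneous (per-cell Poisson)
point process; sequential-occasion Poisson detections with sex-specific
rates and the bk response; and replicate-PCR genotyping with per-sample
failure, per-replicate allelic dropout (heterozygotes only) and
false-allele substitution to a uniformly random other panel allele, plus
Y-marker replicates with the same dropout.  Defaults mirror the field
conditions at roughly a third of the spatial scale — 100-km network, 20
detectors every ~5 km, 8 occasions, lambda0 = 0.3, sigma = 5 km,
D = 0.5/km, dropout 0.29, false-allele 0.05 — which keeps a single
maximum-likelihood fit well under a second.  Per-sample success defaults
to 0.3, a realistic screening pass rate for fecal DNA in harsh
environments.

Two-population draws use a Balding–Nichols-style model: per-locus
ancestral frequencies from a Dirichlet, population frequencies from
`Dirichlet(p (1-F)/F)` at target differentiation F, genotypes by
Hardy–Weinberg draws.

What the simulator does **not** emulate: animal movement within a survey
(centers are fixed points, detections conditionally independent given the
center), open-population dynamics, heterogeneity in detector attractiveness
beyond effort, fragment-size artifacts in allele calling, or spatial
correlation of genotyping failure.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
transience, density-dependent space use, or lab artifacts outside the
dropout/false-allele model.

## Validation studies and problem sizes

The repeatable studies in `linscr.experiments` (also run by
`scripts/acceptance.py` and `analysis/06_validation.py`):

* **Parameter recovery** — 50 seeded simulate-and-refit runs at the
  default scenario with 500-m state-space spacing (sigma/spacing = 10,
  ample for a smooth kernel); median relative bias of D, lambda0, sigma
  within a few percent and D CI coverage near 0.95.
* **GOF calibration** — 20 meta-replicates of 25 bootstrap replicates on
  a half-scale scenario (50-km, 10 detectors, 6 occasions).
* **FST recovery** — 200 two-population draws at target 0.10 (30 loci,
  50/50 individuals); the mean theta lands within ~0.001 of target.

## Known limitations

* Genotyping error is handled by the dual conservative/lenient matching
  rules, not by partial-identity or random-thinning observation models;
  residual ghost individuals inflate density slightly, which is exactly
  why both rules are reported.
* No ecological (least-cost) distance: movement off the network is
  assumed negligible.
* The Wald/delta intervals are asymptotic; with very few spatial
  recaptures sigma is weakly identified (the fit warns).
* The matching rule is quadratic in samples; fine at field scales (a few
  hundred genotyped samples).
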