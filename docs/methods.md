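# Methods

`sitefidelity` implements an individual-level analysis of foraging
specialization in a central-place foraging seabird (modelled on black-legged
kittiwakes breeding in Svalbard): boldness is scored from novel-object tests,
foraging sites are located with a movement hidden Markov model, site fidelity
is quantified by a randomization similarity index, and specialization is
compared between bold and shy birds through repeatability of trip metrics.
All stages run end-to-end on synthetic data with known ground truth, so every
estimator has a parameter-recovery test surface.

## Track processing

GPS fixes are filtered against a 300 m buffer around the colony; a foraging
trip is a maximal run of consecutive outside-buffer fixes whose elapsed time
(first to last outside fix) exceeds 1 h. Runs touching the start or end of a
recording are incomplete (logger failure). Trips are linearly interpolated in
time to a regular grid (10 min during incubation, 2 min during chick
rearing), anchored at the first fix, with the final fix appended when
off-grid.

Trip metrics are cumulative path length (km), duration (h) and maximum
colony distance (km). Incomplete trips contribute no distance or duration;
their maximum range is kept only if the final fix lies within 75% of the
trip's maximum colony distance — i.e. the bird had essentially returned
before the recording stopped.

Distances use the haversine formula on a sphere of radius 6371 km; at these
ranges (< 300 km) the spherical error is negligible. Turning angles are
signed changes in great-circle bearing between successive steps,
counter-clockwise positive, wrapped to (-pi, pi]; the first step of each
trip has no angle and is treated as missing, not dropped.

Two operational rules are deliberately explicit because they are otherwise
matters of convention: a trip consists of outside-buffer fixes only (no
interpolation onto the buffer circle), and the 1 h rule uses the elapsed
time between the first and last outside fix.

## Movement HMM

Step lengths follow state-specific gamma distributions parameterised by mean
m and standard deviation s (shape m^2/s^2, scale s^2/m); turning angles
follow state-specific von Mises distributions (mean mu, concentration
kappa >= 0). The hidden chain has initial distribution delta and transition
matrix Gamma. Free parameters for S states: (S-1) + S(S-1) + 4S.

The pooled log-likelihood (each trip an independent chain sharing
parameters) is computed by the scaled forward algorithm, vectorised across
trips, and maximised directly by L-BFGS-B on unconstrained working
parameters (log for positive quantities, row-wise multinomial logits for
delta and Gamma), with multi-start jitter (default 5 restarts, SD 0.3 in
working space; the first start is unjittered). Model order is chosen by AIC;
decoding uses the Viterbi algorithm. Both the forward likelihood and Viterbi
are verified against exhaustive enumeration of all S^T paths at T = 8.

Numerical choices:

* zero or near-zero step lengths are floored at 0.1 m before evaluating the
  gamma density, keeping the likelihood finite without a zero-inflation
  component (out of scope here);
* default starting step means are (300, 60, 15) m per minute scaled by the
  fix interval — e.g. (3000, 600, 150) m at 10-min fixes — with SDs equal to
  the means, angle means (0, 0, pi), concentrations (5, 1, 0.5), uniform
  delta, and 0.9-diagonal Gamma; all are config-overridable;
* the first angle of each chain contributes step density only.

States are labelled automatically after fitting: *travelling* is the state
with the largest mean step; among the remainder, *foraging* is the state
whose angle distribution concentrates away from zero — the largest
kappa (1 - cos mu) / 2, the turn-reversal signature of area-restricted
search — and *resting* is what is left. Ranking by turn reversal rather than
by "smallest step mean among non-concentrated states" avoids mislabelling a
low-concentration resting state (short drifting steps, diffuse angles near
zero) as foraging.

A fix takes the state of the step leaving it; the final fix inherits the
last step's state. Maximal runs of foraging-state fixes become foraging
sites, summarised by the arithmetic mean of member latitudes and longitudes
and the midpoint of the run's time span. Trips whose decoded path contains
no foraging fix show no area-restricted search and are removed from all
analyses, with the count reported.

## Boldness

Each novel-object test records the proportions of a 60 s exposure spent in
five mutually exclusive states, from sitting tight to leaving the ledge. A
PCA on the covariance matrix of the centred, unscaled proportions collapses
them to PC1, oriented so sitting loads positively (bold = high). Covariance
rather than correlation PCA is used because the sum-to-one constraint then
guarantees a zero-variance fifth component with loadings 1/sqrt(5) ~ 0.447
on every behaviour — a structural property the tests assert on arbitrary
compositional data.

Adjusted repeatability of PC1 is R = s2_bird / (s2_bird + s2_res) from a
linear mixed model with a random intercept per bird and fixed covariates
(test date, breeding stage, observer, test number where they vary). The
model is fitted by a profiled REML specific to the single-random-intercept
structure (the covariance inverse and determinant decompose per bird, so
REML reduces to a one-dimensional search over the variance ratio); it
matches a general mixed-model fitter to ~6 decimals and makes the
parametric bootstrap (default 1,000 refits) cheap. Confidence intervals are
bootstrap percentile intervals; the p value is a likelihood-ratio test of
the between-bird variance against the boundary mixture
0.5 chi2(0) + 0.5 chi2(1). The response is standardised internally so R is
exactly invariant to affine rescaling.

One boldness value per bird comes from an ordinary linear model of PC1 on
bird identity (factor, no global intercept) plus centred covariates;
covariates aliased with bird identity (e.g. one observer per colony) are
dropped with a logged warning. Birds strictly above the median boldness are
*bold*, the rest *shy* — the bird at the median goes to shy, an explicit tie
rule.

## Site fidelity

With each foraging site in turn as the focal site, the randomization pairs
it with one same-bird site from a different trip (within pair, uniform) and
one site from each other bird of the same colony and breeding stage (between
pairs, uniform per bird). A between pair scores 1 when the within site is
strictly closer to the focal site than the other bird's site; ties score 0.
The per-bird proportion of 1s is the (already inverted) similarity index on
[0, 1]. Only birds with sites on more than one trip are focal; single-trip
birds still donate between pairs. Breeding stages are analysed separately.

Per iteration, pooled outcomes are fitted by a binomial GLM with bird
identity as a factor (no global intercept) plus the centred within-pair time
difference in days; each bird's fidelity is the inverse logit of its
coefficient (i.e. at the average time difference), with a delta-method
standard error. Birds with all-0 or all-1 outcomes (complete separation) are
clamped to 1/(2m) and 1 - 1/(2m) with m their outcome count, flagged, and
excluded from the GLM. With the time covariate disabled the estimator
reduces to the raw per-bird proportion, which is what the exhaustive-pairing
oracle checks (the Monte-Carlo mean is then linear in the outcomes, so it
converges to the enumerated expectation). The default is 1,000 iterations;
iteration i draws from an RNG substream derived from (seed, i).

The time difference attached to a pair is |days| between the focal and
within sites: the within pair is what carries the fidelity signal that
temporal proximity could modulate. Which pair the original index intended is
under-specified; this choice is a documented convention, as is reporting
per-bird estimates on the proportion (not logit) scale.

Fidelity is then modelled per iteration by a linear model with boldness,
sex, colony and date as fixed effects. The boldness x sex and boldness x
colony interactions are screened on the iteration-mean fidelity and dropped
when non-significant (F test, alpha = 0.05). Term significance uses F
comparisons of models with and without each term, averaged over iterations.
Coefficients are summarised three ways: the across-iteration mean; the
2.5%/97.5% iteration quantiles ("estimate range" — this captures
randomization noise only and is typically much narrower than the sampling
uncertainty); and the mean model SE. Calibration statements (does a null
slope's interval cover zero?) use mean +/- 1.96 x mean SE, because the
iteration quantiles have no frequentist coverage over replicate studies by
construction.

## Repeatability comparison and spatial partitioning

Trip distance, duration and maximum range are log10-transformed and their
repeatability estimated separately for bold and shy birds (one row per trip;
same REML estimator as above, no covariates), with 84% and 95% bootstrap
percentile intervals. Two groups are declared different when their 84%
intervals are disjoint (a shared endpoint counts as overlap); for normal
estimates with equal SEs this rule is a z test at just under the 0.05 level
(Monte-Carlo type-I error ~0.047, recomputed by `scripts/acceptance.py`).

Spatial partitioning is probed by linear mixed models of site central
latitude (log2-transformed) and longitude (square-root-transformed) on
boldness, sex, colony and date, with random intercepts for trip nested
within bird. REML estimates are reported; fixed-term tests are
likelihood-ratio comparisons of maximum-likelihood refits. The square root
requires positive longitudes (true around Svalbard); negative longitudes get
an automatic, logged +360 offset. Degenerate hierarchies are reduced
automatically: the trip component is dropped when no trip has several sites
or no bird several trips, and the model collapses to OLS when no bird has
several sites.

## Synthetic data

The generator emulates the study's sampling design with known ground truth.

*Tracks.* Each bird makes repeated trips from its colony: a directed out-leg
of travel-state steps toward a target, a dwell of 20-40 steps alternating
foraging and resting states (turning by the state's von Mises draws under
the package's angle convention), and a return leg, with a few at-colony
fixes between trips. Positions are propagated on a local tangent plane and
converted to latitude/longitude (adequate below ~300 km). Step lengths are
exact gamma draws from the generating state; the single synthetic closing
step back to the colony is marked so per-state accounting stays exact.
Targets implement fidelity: with per-bird probability `fidelity_level` a
trip revisits the bird's preferred site (drawn uniformly by area in a
5-60 km annulus), otherwise a fresh annulus site.

*Personality.* A latent per-bird boldness with between-bird variance share
equal to the configured repeatability (default 0.678) drives a
sitting-to-leaving softmax gradient in each test's five proportions, which
therefore sum to one exactly; a small logit jitter (SD 0.05) keeps the
composition covariance at rank 4 without materially inflating within-bird
variance. Small habituation (test number) and observer effects are added for
the adjusted models to remove. Birds receive 1-4 tests with frequencies
matching a field campaign where most birds are tested once.

*Defaults as study conditions.* Four Svalbard-like colonies, 12 birds per
colony, 3 incubation trips per bird at 10-min fixes; generating HMM with
step means (3000, 300, 60) m/fix, SDs (1500, 250, 50), angle means
(0, pi, 0), concentrations (8, 1.5, 0.3), persistent transitions
(0.85-0.92 diagonal); baseline fidelity 0.6 with slope 0.086 per boldness
unit linking the two traits. A site-level shortcut generator
(`simulate_sites`) draws sites directly from the target process (scatter SD
1.2 km) for analyses that do not need track decoding.

What the generator does *not* emulate: GPS position error, irregular or
missing fixes, environmental covariates (bathymetry, fronts, wind, tides),
chick-age dynamics, land masking, or fjord-specific differences in movement
scale. Passing recovery tests therefore shows the estimators are correct
under the stated model, not that the model captures every feature of field
data.

## Problem sizes used in tests

Tests run the estimators at reduced scale chosen for a desk machine: HMM
recovery at 20 tracks x 500 steps (single start from the defaults),
randomization oracles at <= 4 birds x 3 trips with 1,000 iterations,
repeatability bootstraps at 150-300 refits, and replicate-study loops at 10-20
seeds. The analysis scripts use 300 randomization iterations and 500
bootstrap refits (`analysis/config.yaml`); library defaults remain 1,000.

## Known limitations

* The HMM uses numerical gradients; fits with many states or very long
  series would benefit from analytic gradients or EM.
* Separation handling in the fidelity GLM is a transparent clamp, not a
  penalised fit; clamped birds are flagged in the output.
* The fidelity model's per-term p value is computed from the
  across-iteration mean F statistic; alternatives (median p, combined
  tests) would be equally defensible.
* Transition probabilities carry no covariates, and step distributions are
  not zero-inflated.
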