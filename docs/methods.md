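# Methods

## Task and conventions

All analyses address cued dual-report recall from multi-item arrays: N = 6
colored, oriented bars on an invisible circle, two retention intervals
("short"/"long") interleaved and balanced within 36-trial blocks, 216 trials
per participant.  Two task configurations are supported: a location cue with
color and orientation reports, and an orientation cue with color and location
reports (color first in both).

Angles are radians in the half-open interval `[-pi, pi)` with `pi -> -pi`.
Bar orientation is unique only over 180 degrees, so orientations are doubled
immediately on load and all internal computation happens on the shared full
circle; the file format stores orientations natively (halved).  Stimulus
features are uniform on the circle subject to pairwise minimum separations of
pi/9 within each dimension (20 degrees; equivalently 10 degrees of native
orientation), sampled by whole-vector rejection (capped at 10^4 attempts).

Dispersion is Fisher's circular standard deviation `sqrt(-2 ln R)`; it is
`+inf` at R = 0, and downstream comparisons must tolerate that value.  The
V-test p-value uses the one-sided large-sample normal approximation
`u = V sqrt(2/n)`; exact small-n tables are out of scope.

## Mixture models

Each report is a mixture of a target component (von Mises centered on the
true target feature), optionally a nontarget component (von Mises around a
nontarget's feature with the *same* concentration as the target component),
and a uniform component.  The joint two-component model estimates
proportions over {TT, TU, UT, UU} plus one concentration per report (5 free
parameters); the joint three-component model adds nontarget responses and
splits the both-nontarget case into matched (NNs, same item) and mismatched
(NNd, two different items) swaps (11 free parameters).  Nontarget and
NNd sub-assignments are weighted uniformly (over nontargets, and over
ordered distinct pairs, respectively) — the maximum-entropy choice.

Fitting is by EM over an atom expansion (every concrete source pair is an
atom within its component); the concentration update inverts the Bessel
ratio A(kappa) = I1/I0 by a piecewise approximation plus Newton steps,
bounded to [1e-3, 1e4] (data concentrated beyond the cap trigger a
degenerate-data warning).  Three restarts (one moment-based start, the rest
random) guard against local optima; proportions live on the simplex by
construction of the E-step.

The correlation strength of a two-component fit is the mean-square
contingency of the 2x2 T/U table,
`Phi^2 = (a_TT a_UU - a_TU a_UT)^2 / (a_T. a_U. a_.T a_.U)`,
0 for independent and 1 for perfectly correlated response types; degenerate
margins return 0 with a warning (the measure is undefined there).  Reference
predictions: independent recall is the outer product of the marginals;
perfectly correlated recall puts `(a_T1 + a_T2)/2` on TT, the rest on UU.

Response classification uses *separate* single-feature fits per report (so
one report's classification cannot bias the other), with hard labels by
posterior argmax; for three-component fits the winning nontarget item is
recorded, enabling error histograms relative to the chosen nontarget's other
feature.

## Neural binding model

A conjunctive population code for feature pair (psi, theta) consists of
M = 32 x 32 idealized neurons on a uniform torus lattice (configurable; the
tests also run 24 x 24).  Item j elicits mean rates proportional to the
product of von Mises tuning profiles in the two dimensions, normalized so
each of the N items contributes exactly gamma/N expected spikes — hence the
population total is exactly gamma for any stimulus, lattice, and N.  The
decoding interval is fixed at 1, so gamma is the expected total spike count
per retrieval episode; only the rate-interval product is identifiable.
Spike counts are independent Poisson.

Retrieval decodes every item's feature pair by maximum likelihood from its
spikes.  Because the log tuning profile is a sum of cosines, the likelihood
separates by dimension and the exact ML decode is the resultant direction of
the spiking neurons' preferred values; zero spikes (or an exactly cancelled
resultant) decode as a uniform random guess.  The item whose decoded cue
feature is closest to the presented cue is selected (ties, a measure-zero
event, fall to the argmin), and its decoded report feature is the response.

Three binding architectures define which populations exist and how retrieval
chains: *spatial* (color x location and orientation x location; nonspatial
features bound only via shared location), *via color* and *via orientation*
(a color x orientation population allows direct nonspatial binding, making
one reported feature an intermediary cue for the other).  Under a location
cue the spatial variant retrieves both reports directly and independently
(fresh Poisson noise per population); under an orientation cue it must chain
orientation -> location -> color.  All variants share gamma and per-dimension
concentrations across their populations: four free parameters.

### Response likelihood

The response density is computed by a deterministic quadrature rather than
Monte Carlo simulation.  Conditional on k spikes, the decoded direction of
one dimension is the direction of a k-step von Mises random walk; since the
von Mises is an exponential tilt of the uniform step distribution, that
direction density is `g_k(theta) ∝ ∫ exp(kappa r cos theta) w_k(r) dr` with
`w_k` the radial density of the classical uniform (Pearson) random walk —
a kappa-independent family computed once by an exact distributional
recursion (k = 2 analytic; each further step adds one uniform unit step on a
512-cell radial grid) and cached.  Rows beyond k = 80 use the asymptotic von
Mises law with Fisher information k kappa A(kappa).  Tables are evaluated on
an adaptive circular grid (at least six points per SD of the most
concentrated spike-count row, capped at 4097 half-circle points).

The per-trial density then follows exactly from the model structure:
`p(report | cue) = sum_{j,k} P(select j, K_j = k) g_k(report - theta_j)`,
where the selection probabilities integrate the per-item absolute
cue-deviation distributions (CDF differences of the g_k tables) against the
survival product of the competing items, on 64 quadratically spaced
selection-distance bins concentrated near zero where precise decodes
compete.  Spike-count coupling between selection quality and report
precision (both share K_j) is retained exactly.  For chained variants the
intermediary feature is itself one of the two reports, and the model treats
the report as equal to the decoded intermediary; the second factor therefore
conditions on the *observed* intermediary report, and no numerical
integration over the intermediary is needed.  Response densities are floored
at 1e-150 (below any attainable density) with a logged warning.

This quadrature was validated against the simulator (which samples the
actual lattice populations): selection probabilities agree to 5e-4 in
aggregate swap rate, and simulated response histograms match the density
with total variation < 0.015 at 40,000 episodes.  Because the likelihood is
deterministic, fits are exactly reproducible.

### Fitting and comparison

Maximum likelihood by Nelder-Mead simplex on log-transformed parameters
(gamma in [0.05, 2000], concentrations in [0.05, 100], soft quadratic
penalty outside), five dispersed restarts with a bounded evaluation budget
(120 per restart) followed by a polish (150 evaluations) of the best start.
Variants are compared by log-likelihood (equal parameter counts); against
the two-component joint mixture (5 parameters) by AIC `2k - 2LL` and BIC
`k ln n - 2LL`.

Identifiability caveat: under a *location* cue the spatial variant's
location concentration enters only through selection errors.  At the
canonical generative parameters below the simulated swap rate is about
0.1%, i.e. roughly two swap events in 2000 trials, so kappa_loc is
essentially unidentified in that design (its profile likelihood is flat
within a few log-likelihood units out to the parameter bound).  Parameter
recovery is therefore demonstrated under the orientation-cue design, where
location is itself reported and all four parameters are informed; the
location-cue design is still the right instrument for *architecture*
comparison, which is what it is used for here.

A second, milder flat direction exists in every design: the per-dimension
precision products gamma kappa_d A(kappa_d) are sharply identified, but
separating gamma from the concentrations relies on O(1/lambda)
spike-count-dispersion effects, worth only about one log-likelihood unit
per ~75% change in gamma at 2000 trials and gamma = 100.  Recovery of the
individual parameters at that size is therefore accurate in most but not
all realizations (observed maximum relative errors range from ~6% to ~76%
across simulation seeds, always with the precision products within a few
percent); the estimator is consistent, and at 20,000 trials the truth
dominates displaced ridge points clearly.

## Model-free swap statistics

Deviations of each response from every nontarget's report feature are
compared against a shuffling null: each replicate permutes the
target-relative nontarget offset configurations across trials within the
same delay condition and recombines them with the actual per-trial response
errors, preserving the error marginal and the separation structure while
destroying any true response-nontarget association.  Defaults: 1000
shuffles, 37 histogram bins.  The summary is the mean absolute deviation
(MAD); chance level for uniform responses is pi/2.  The cue-distance
analysis assigns each nontarget to one of eight equal bins of absolute
cue-feature distance to the target spanning [minimum separation, pi] and
compares per-bin MADs with their shuffle expectations.

A property worth knowing when interpreting these statistics: minimum
feature separation makes a response located *at* one nontarget lie slightly
farther than chance from the remaining nontargets (mean pairwise item
distance 1.72 vs chance pi/2 = 1.57).  Injected matched swaps therefore
depress the overall MAD by roughly half the naive expectation, and elevate
far cue-distance bins slightly above chance; the discriminating signature
of cue-similarity-driven swaps is the strong depression of the *nearest*
bin with no depression in the far bins.

## Synthetic studies: what they show

The canonical generative parameters are gamma = 100 expected spikes per
population and episode with concentrations (location, color, orientation) =
(8, 4, 4) — a regime with precise location coding and moderate nonspatial
precision that reproduces the qualitative phenomena of interest (near-zero
error correlation under a location cue; Phi^2 higher by > 0.3 under an
orientation cue; cue-similarity-dependent swaps).  These synthetic
participants are *idealized*: all trials are completed, attention is
constant, responses equal decoded values with no motor noise, and all
participants share one parameter set.  Recovery and selection-consistency
results therefore establish the *internal* correctness and statistical
power of the estimation machinery at realistic trial counts, not the
validity of the model for any particular empirical dataset.

Problem sizes used by the test suite and the acceptance script — 20
simulated participants of 216 trials each per architecture for model
selection, 2000 trials for binding-model recovery, 5000 for mixture
recovery, 10^4 trials for swap-statistic calibration, 10^6 draws for the
circular-SD oracle — were chosen so each check's sampling noise is well
inside its tolerance.

## Known limitations

- Memory dynamics over the delay are not modeled; delay conditions are
  handled by fitting separate parameter sets per condition.
- The likelihood treats spikes' preferred values as continuous von Mises
  draws (the infinite-lattice limit); with the default 32 x 32 lattice the
  discrepancy is negligible for concentrations up to a few tens, and fits
  bound concentrations at 100.
- The EM mixture fits and the simplex binding-model fits find local optima;
  restarts make failures rare but not impossible.
- Phi^2 is undefined at degenerate margins (returned as 0 with a warning);
  with very precise synthetic data the two-component fit can drive uniform
  margins near zero, making Phi^2 estimates unstable at small n.
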