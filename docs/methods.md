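# Methods

`camtrapocc` implements the statistical workflow of a single-season
camera-trap occupancy study of a small Andean felid: detection-history
construction, single-species occupancy models with imperfect detection
(maximum-likelihood and MCMC engines), two-species conditional
co-occurrence in the ψBa parameterization, model selection by AICc and
PSIS-LOO elpd, MacKenzie–Bailey goodness of fit, and spatial residual
diagnostics. Everything is exercised end-to-end on synthetic data with the
study design's statistical structure.

## Detection histories

Photographic records (station, species, timestamp) are reduced to
*independent detections* by pooling within station × species × calendar
day and keeping the earliest record — a fixed 24-h calendar bin rather
than a rolling window, so the operation is order-independent and
idempotent. Guild pooling (e.g. a single killers/predators class, or all
small mammals as prey) relabels records *before* the independence filter,
so a guild detection day is any member's record day.

Occasions are consecutive 7-day blocks anchored at each station's own
activation date, not at a calendar grid: the reserves ran in disjoint
calendar windows, and a shared grid would manufacture structural
missingness. The final partial block keeps its remaining days as effort,
which is then available as a detection covariate. A cell is missing
exactly when its effort is zero (camera inactive for the whole block);
records falling outside a station's deployment window are dropped with a
warning (camera-clock artifacts), not treated as errors.

## Covariates

Numeric covariates are z-scored, (x − mean)/SD with the sample SD.
Collinearity is screened with pairwise-complete Pearson correlations; a
pair is flagged when |r| is *strictly* above 0.65, and the tool only
reports — which member of a flagged pair to drop is an ecological
judgement left to the analyst. Correlated landscape metrics are summarised
by PCA on the correlation matrix (the metrics are heterogeneous in units,
so covariance-matrix PCA would let one metric's scale dominate);
components with eigenvalue > 1 are retained (Kaiser rule). PCA signs are
arbitrary, so PC1 is anchored by forcing the first ("forest amount" style)
metric's loading negative: negative scores then read as more and
better-connected forest. Quadratic terms square the already-scaled
covariate and are not re-scaled, keeping the turning point −β₁/(2β₂)
interpretable on the scaled axis. Categorical covariates are dummy-coded
against the alphabetically first level.

## Single-species model

The hierarchy is z_i ~ Bernoulli(ψ_i), y_ij | z_i ~ Bernoulli(z_i · p_ij),
with logit-linear submodels logit(ψ_i) = x_i'β, logit(p_ij) = w_ij'α. The
marginal (z-integrated) site likelihood

ψ_i ∏_j p_ij^{y_ij}(1 − p_ij)^{1−y_ij} + (1 − ψ_i)·[no detections]

is computed in log space with a log-sum-exp for the all-zero branch;
missing occasions contribute nothing. Linear predictors are clipped to
|η| ≤ 35 before exponentiation — overflow-free with no measurable bias at
double precision. Because camera stations are much smaller than a felid
home range, ψ is reported as *habitat use* and p as *intensity of use*;
fit reports carry those labels.

**ML engine.** BFGS with the analytic gradient (which reduces to
∂ℓ/∂β = X'(c − ψ) and ∂ℓ/∂α = Σ c_i(y_ij − p_ij)w_ij, where c_i is the
conditional occupancy given the history), from five deterministic starts:
intercepts at the logit of the naive occupancy/detection rates offset by
(0,0), (±1,±1), slopes at zero. Convergence requires gradient norm
< 1e−5; SEs come from the inverse numeric-differenced observed
information; a boundary warning fires when any fitted probability exceeds
0.9999. Deterministic starts were preferred over random restarts for
reproducibility.

**MCMC engine.** Adaptive random-walk Metropolis on the marginal
log-posterior; priors are Normal(0, 2.5) on every coefficient, which is
effectively uninformative on the scale of z-scored covariates while
avoiding separation pathologies. The proposal is a diagonal Gaussian
scaled by the ML standard errors; a global scalar adapts toward the 0.234
optimal acceptance rate during burn-in (Robbins–Monro on batches of 50)
and is frozen afterwards. Defaults are 3 chains × 30,000 iterations with
the first half discarded, matching the study protocol; the test suite and
drivers use shorter chains (4,000–10,000) after checking that split R-hat
stays below 1.1 at those lengths for the models involved. Hamiltonian-
sampler tuning parameters (e.g. a target adaptation acceptance of 0.99)
have no direct random-walk analogue; acceptance-rate targeting is the
substitute. Credible intervals are equal-tailed 2.5/97.5% posterior
quantiles.

R-hat is the split-chain Gelman–Rubin factor, clipped below at 1 (values
under 1 are estimation noise); ≥ 1.1 attaches a non-fatal convergence
warning.

## Two-species conditional co-occurrence (ψBa parameterization)

An asymmetric dominant (A) / subordinate (B) model with eight parameters:
ψA; ψBA and ψBa (B's occupancy given A present/absent); pA and pB
(detection at single-species sites); and rA, rBA, rBa at both-present
sites, where B's detection on occasion j is rBA if A was detected on that
same occasion and rBa otherwise. The same-occasion time grain for the
rBA/rBa switch is the standard convention for this parameterization; the
generator in `simulate` uses the identical rule, and an enumeration test
confirms generator/likelihood agreement. The site likelihood sums the four
latent states (both, A-only, B-only, neither), each weighted by its
occasion-product detection term.

The 2×2 variant grid — occupancy conditional or not (ψBA ≠/= ψBa) crossed
with detection conditional or not (pA ≠/= rA, pB ≠/= rBA ≠/= rBa) — gives
models with 4, 5, 7 and 8 parameters; covariates may enter the ψB-side
linear predictors (shared slopes on ψBA and ψBa), mirroring the practice
of carrying the best single-species occupancy covariates into the
co-occurrence stage. Fitting is ML on logit-transformed parameters with
the same multi-start scheme; selection uses AICc with n = sites, the
small-sample convention for site-indexed occupancy data.

Derived summaries: the species interaction factor
Φ = ψA·ψBA / (ψA · (ψA·ψBA + (1 − ψA)·ψBa)) — the ratio of joint
occupancy to the product of the marginals, 1 under independence — and the
detection interaction factor δ = rBA/(rA·rBa). Both are ratio statistics
with skewed sampling distributions, so uncertainty comes from a seeded
parametric bootstrap (default 500 refits) rather than the delta method.
Note that with this δ definition, values far from 1 arise whenever rA is
small even under moderate detection dependence; δ is reported only for
detection-conditional variants.

## Model selection and goodness of fit

AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1), Akaike weights exp(−Δ/2)
renormalised, competitive set at Δ < 2. For Bayesian fits, elpd is
estimated by PSIS-LOO: raw importance ratios are reciprocal pointwise
likelihoods, smoothed by fitting a generalised Pareto to the largest 20%
of weights (via `arviz.psislw`); sites with shape k̂ > 0.7 are flagged.
Δelpd against the best model carries SE(Δ) = √(n·var(pointwise
differences)), and a model is flagged "less support" when |Δ| exceeds that
SE. elpd weights are exp-renormalised (pseudo-BMA) — the simplest
defensible scheme where none is prescribed.

The p-first sequential strategy ranks p(term)ψ(.) candidates (plus the
null) first, fixes the winning detection structure, then ranks ψ(term)
candidates (plus the null). It is a pure function of (data, candidates,
seed).

The MacKenzie–Bailey statistic groups sites into cohorts sharing a
missingness pattern; within a cohort the expected count of each *observed*
unique history is E_h = Σ_i Pr(h | θ̂, x_i), plus one pooled
never-observed cell per cohort with O = 0 and E = N − ΣE_h — avoiding
enumeration of all 2^J histories. With many occasions the per-history
expectations are tiny and the raw χ² is huge; the statistic is therefore
only interpreted against its own simulated reference distribution, never
against a χ² table. Two references are provided: a parametric bootstrap
around the MLE (replicates refitted, starting from the observed estimates
for speed and stability) and a posterior-predictive check (replicate and
observed discrepancies compared at each sampled draw; Bayesian P =
proportion of draws with replicate > observed, acceptable when > 0.05).
Both report the lower tail too, so underdispersion is visible rather than
corrected away. A zero-proportion discrepancy (share of surveyed cells
with no detection) is available as an alternative statistic.

## Spatial diagnostics

Occupancy residuals are conditional-occupancy minus modelled ψ: for ML
fits, Pr(z_i = 1 | history) − ψ̂_i; for Bayesian fits, the mean over draws
of z_i^(s) − ψ_i^(s) with z sampled from its conditional. Global Moran's I
uses row-standardised inverse-distance weights (parameter-free default;
haversine distances for lon/lat coordinates, Euclidean for planar) with
normal-approximation inference, E[I] = −1/(n−1). Scale dependence is
shown by a distance-binned correlogram — equal-count bins, binary in-bin
weights, 2.5/97.5% envelope from residual permutations — substituting for
a smoothing-spline correlogram: the same inferential target without a
smoothing-basis dependency. Bins with fewer than 20 pairs are flagged
unreliable.

## Synthetic data

The generators invert the fitted models exactly (draw z, then y given z;
draw the four-cell joint state, then paired detections with the
same-occasion rBA/rBa switch), so empirical history frequencies match the
likelihood by construction — verified by enumeration at J ≤ 3. The
study-design preset uses 58 stations, 19 weekly occasions, habitat use
0.68 and weekly detectability 0.15 (the survey's null-model estimates),
with per-station deployment lengths Normal(130, 24) truncated at 30 days
converted to trailing missingness; only the mean ± SD of deployment length
is known, hence the truncated normal. Random mid-survey gaps (camera
theft/failure) are available via a missingness rate.

A separate deterministic fixture reproduces the survey's printed totals
(10,689 trap-nights, 74.1 km² of camera-array MCP, per-reserve weekly
detection counts) from constructed stations and records; it is a synthetic
stand-in — station layouts are rectangles whose convex hull equals the
printed MCP areas, and detections are laid out to match the printed
occasion- and day-level counts. The two printed prey totals (463 daily
detections in the text vs 965/423 implied by the per-reserve table) are
inconsistent at source; the package reports both resolutions and anchors
on neither.

What the generators do *not* emulate: spatially autocorrelated occupancy
surfaces, animal-movement-driven detection correlation, species
misidentification, and camera-level detection heterogeneity beyond the
covariates supplied. Passing recovery and calibration tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every field pathology.

## Problem sizes and numerical choices

The test suite runs simulations at sizes chosen to make the statistical
checks sharp but cheap: parameter recovery at n = 500 × J = 19 (single
species, tolerance 0.05) and n = 800 × J = 12 (eight-parameter
co-occurrence, tolerance 0.07); Wald coverage over 50 replicates at
n = 200; GOF calibration over 20 runs × 200 bootstrap replicates at
n = 100; misspecification power over 10 MCMC replicates at n = 200;
selection consistency over 25 replicates at n = 400 with the ML engine
(the Bayesian elpd route is checked once at n = 300 — repeating it 25
times would add runtime without changing what is verified). Enumeration
oracles (likelihood normalization, generator agreement) use exact
tolerances of 1e−10.

## Known limitations

- No random-effects, multi-season, or spatially explicit occupancy; the
  study itself discarded its random-effect variant (too few factor
  levels).
- The co-occurrence stage is frequentist only; ≥3-species models are out
  of scope.
- The MB χ² is sparse-table sensitive by construction; use the simulated
  reference, and prefer the zero-proportion variant only for gross checks.
- The random-walk sampler is adequate for the ≤ ~8-coefficient models used
  here but will mix slowly for much larger covariate sets.
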