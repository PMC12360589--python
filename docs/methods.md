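# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Events, independence, effort

A raw record is (camera, species, timestamp). Within each camera × species
stream sorted by time, a photo opens a new independent event iff its gap
from the *previous photo of the current event* is at least the window
(default 30 minutes). The window is rolling: a burst at 00:00, 00:10,
00:45 yields events at 00:00 and 00:45, because 00:10 merged into the
first event and 00:45 is 35 minutes after it. A gap of exactly the window
starts a new event; the convention is stated because published
descriptions of the rule are silent on the boundary. Filtering is
idempotent and the retained count is non-increasing in the window.

Effort is counted at day granularity: a trap night is one camera active
for any part of one calendar day, clipped to the season window (summer
1 Jul–31 Aug, autumn 1 Sep–31 Oct). RAI = events / trap nights × 100 is
reported on pooled effort; since only camera-level replication exists, the
SE is the among-camera standard deviation of per-camera indices divided by
√(number of cameras). Day-granularity effort may differ slightly from
bookkeeping that drops partial malfunction days; the choice is the field
standard and is applied consistently.

## Diel activity

Clock times map to angles t = 2π·(seconds since midnight)/86400; no
solar-time correction is applied. The activity curve is a von Mises kernel
density estimate,

f̂(t) = (1/n) Σᵢ exp(κ cos(t − tᵢ)) / (2π I₀(κ)),

with κ from a two-step plug-in: the sample's ML von Mises concentration
(Fisher/Best approximation) capped at κ̂ ≤ 3, then the Taylor (2008)
circular bandwidth rule κ = (3 n κ̂² I₂(2κ̂) / (4 √π I₁(κ̂)²))^{2/5} —
the convention of the standard activity-overlap software. The cap keeps
multimodal samples from driving the rule to needle-like kernels. The
`adjust` multiplier scales the kernel concentration directly (values > 1
sharpen); the default is 1.

Overlap uses the coefficient of overlapping Δ = ∫ min(f₁, f₂). Δ̂₄
evaluates the fitted densities at the observed points of both samples:
Δ̂₄ = ½[ meanᵢ min{1, f̂₂(t₁ᵢ)/f̂₁(t₁ᵢ)} + meanⱼ min{1, f̂₁(t₂ⱼ)/f̂₂(t₂ⱼ)} ].
It is the recommended estimator for samples of 75+; a warning suggests
Δ̂₁ (grid integration of min(f₁, f₂)) below that. Densities that
underflow at an observed point are floored at the smallest positive
double; the ratio then clips at 1. Confidence intervals come from a
smoothed bootstrap — resamples are drawn from each fitted density (data
point plus kernel noise), bandwidths re-estimated per resample, percentile
interval over ≥ 200 replicates, deterministic given the seed.

Watson's two-sample U² is computed over the pooled sorted sample:
U² = (n₁n₂/N²) Σₖ (dₖ − d̄)², with dₖ the running difference of the two
empirical CDFs. The statistic is symmetric in the samples and invariant
under common rotation (to floating-point roundoff; summation order changes
under rotation, so identity is asserted at 1e-12, not bitwise).
Significance is read from the asymptotic critical values 0.152 / 0.187 /
0.268 / 0.385 for α = 0.10 / 0.05 / 0.01 / 0.001, reported as a bracket;
an optional permutation p-value (1 + #{U²\* ≥ U²}) / (1 + M) shuffles the
pooled labels. Ties across samples are broken by placing sample-1 points
before coincident sample-2 points in the pooled sort; because the
classical statistic assumes continuity, the permutation p is recommended
whenever ties exist.

## Detection histories

Each season has six 10-day occasions (days 1–10, 11–20, 21–30 of its two
months); day 31 belongs to no occasion, so every month contributes exactly
30 survey days. A site is one camera-year: the three study years are
pooled into a single-season design with year as a site covariate, matching
the small-sample design the package targets (13–14 cameras per year,
39 camera-years). A cell is 1 if the site had ≥ 1 independent event of the
species in the occasion window, 0 if none although the camera was active
at least one day of the window, and missing only when the camera was
inactive for the whole occasion. Coding a partially active occasion as
surveyed rather than missing is a deliberate choice (the alternative
discards data); it is the one occasion-level convention a reanalysis might
reasonably vary.

Continuous covariates (altitude, slope) are z-scored with the sample
standard deviation (ddof = 1); categorical references are habitat BF and
the earliest year.

## Single-species occupancy

Zero-inflated detection likelihood with logit links on ψ and p; all
covariates are site-level, so p is constant across occasions within a
site. Candidate models allow at most one categorical (year or habitat) and
one continuous (altitude or slope) term per parameter — 9 structures per
parameter, 81 models. AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) uses n = sites
with ≥ 1 surveyed occasion. Optimization is L-BFGS-B with numerical
gradients from 5 dispersed starts (seeded; the first start is the zero
vector), tolerance 1e-8 on the objective; small-sample likelihoods can be
multimodal near the boundary, hence the restarts. SEs come from the
inverse of the numerically differentiated observed information; a singular
Hessian yields undefined (NaN) SEs with the fit retained; boundary
estimates are reported, not truncated. Wald p-values use the standard
normal reference.

Models within ΔAICc < 2 are competitive. Akaike weights are computed over
the full converged set; model averaging is *conditional*: each coefficient
is averaged over the competitive models containing it with weights
renormalized in that subset, and the unconditional SE is
√(Σ w(se² + (β − β̄)²)). Conditional averaging is the convention
consistent with reporting terms that appear in only some competitive
models with finite SEs; full-set zero-substitution averaging would shrink
such terms toward zero.

## Two-species occupancy and SIF

The ψBa/rBa parameterization conditions the subordinate species B on the
dominant species A: occupancy ψBA/ψBa on A's presence, detection rBA/rBa
on A's presence and *same-occasion* detection, pB when A is absent. The
site likelihood mixes the four latent states; a detection of a species
absent in a state zeroes that state's contribution; missing occasions
contribute no factor; all-missing sites contribute nothing and are
excluded from the AICc sample size. When ψBA = ψBa and pB = rBA = rBa
(and rA = pA), the joint likelihood factorizes exactly into the two
single-species likelihoods — this identity is a core regression test.

Occupancy carries no covariates in this family. Detection covariates
follow a shared-offset design: each of the five detection classes (pA, pB,
rA, rBA, rBa) keeps its own intercept; year enters as offsets shared
across classes and species; altitude (when included) as one shared slope.
This is the only structure whose parameter counts match the 2 × 2
constraint grid bookkeeping (e.g. ψ-constrained + free detection + year =
2 + 5 + 2 = 9; fully constrained + year = 7), and it produces distinct
per-class, per-year real-scale estimates. Whether year offsets should be
shared across species is a genuine design inference; sharing is the
parsimonious reading consistent with those counts. The candidate set for
selection is the 2 × 2 constraint grid crossed with detection covariate
sets {year} and {year, altitude} — 8 models.

The species interaction factor is implemented as
φ = ψBA / (ψBa + ψA(ψBA − ψBa)), algebraically identical to the display
form ψA·ψBA / (ψA·(ψA·ψBA + (1−ψA)·ψBa)) — the denominator is ψA times
the marginal occupancy of B and the leading ψA cancels. The cancelled form
is used because ψBA = ψBa then gives exactly 1.0 in floating point (the
difference is exactly zero), and the delta-method gradient components for
ψBA and ψBa cancel exactly under the shared-parameter constraint, so a
constrained fit reports SIF = 1.0 ± 0.0 rather than 1 ± ε. φ is undefined
at ψA ∈ {0, 1} (explicit error).

## Synthetic-data generator

The generator inverts the two-species model: latent states per camera-year
site from the four-state weights, per-occasion detections with the
state-dependent probabilities, year effects added on the logit scale, and
a zero-truncated Poisson number of events (default mean 1.5) per detected
site-occasion — a detected occasion must contain at least one event. Event
times of day are drawn from per-species, per-season von Mises mixtures
chosen to emulate a crepuscular dominant species (dawn/dusk peaks) and a
subordinate that is cathemeral in summer and nocturnal in autumn. Default
generating values (ψA = 0.85, ψBA = ψBa = 0.78, 2015 detection intercepts
pA = 0.12, pB = 0.03, rA = 0.14, rBA = 0.23, rBa = 0.29, year offsets
+0.9 / +1.8 logits for 2016/2017) reproduce the reference study's scale:
high, stable occupancy for both species with detection rising across
years. Deployments cover 1 Jul–31 Oct; with probability 0.1 a camera drops
out for 10–40 days, exercising the missing-occasion code path. Covariates
are uniform on altitude 600–1600 m and slope 2.2–37.1°, habitat
multinomial over {BF, CF, RF}.

Randomness is keyed: every (purpose, site, year) tuple derives its own
generator from the master seed, so identical configs give byte-identical
outputs and enlarging the design leaves existing sites' draws untouched.

What the generator does *not* emulate: site covariates have no effect on
occupancy or detection (year is the only acting covariate), there is no
spatial autocorrelation between nearby cameras, no animal movement or
serial dependence beyond the event-burst option, and diel profiles do not
shift with deer abundance. Tests passing on these data therefore establish
the estimators' correctness under the model's own assumptions, not
robustness to the violations real camera-trap data exhibit.

## Problem sizes used in the checks

The oracle-equivalence check fits 20 constant-model datasets of 50 sites ×
6 occasions against a 200 × 200 grid search with one local refinement pass
(grid resolution 2.5e-4, below the 1e-3 comparison tolerance). Parameter
recovery uses 50 replicates of 500 single-year sites from ψA = 0.7,
ψBA = 0.5, ψBa = 0.9 with detection 0.3–0.5, comparing replicate means to
truth at 3 Monte Carlo SEs. Watson calibration uses 500 null sample pairs
of n = 30 with 99 permutations each. These sizes give stable checks at
interactive runtimes.

## Known limitations

* Detection covariates are site-level only; occasion-varying covariates
  (date, temperature) are not supported.
* The two-species family fixes the direction of asymmetry (A dominant);
  the reverse conditioning is out of scope.
* No goodness-of-fit bootstrap (MacKenzie–Bailey) and no multi-season
  (colonization/extinction) models.
* The Watson bracket relies on the asymptotic table; for samples under ~8
  per group use the permutation p-value.
* RAI is an index, not a density estimate; no detectability correction is
  applied or implied.
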