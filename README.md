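# sympatry

Camera-trap co-occurrence analysis for pairs of sympatric species: do two
species that share a landscape segregate in **time** (diel activity) or in
**space** (site use), once imperfect detection is accounted for?

The package implements the full analysis chain used in camera-trap studies
of interacting ungulates (the motivating system is a dominant deer and a
subordinate serow surveyed July–October over three years at 39 forest
camera sites), and ships a synthetic-study generator with known ground
truth so the entire pipeline runs and is testable offline.

## What it computes

**Independent events and relative abundance.** Raw photo records are
collapsed with the 30-minute independence rule (rolling window per
camera × species stream), then summarized as the relative abundance index

    RAI = (independent events) / (camera-trap days) × 100,

per species, season (summer = 1 Jul–31 Aug, autumn = 1 Sep–31 Oct) and
year, with an among-camera standard error.

**Diel activity overlap.** Event times of day are angles on the circle;
activity curves are von Mises kernel density estimates with a plug-in
bandwidth (ML concentration capped at κ ≤ 3 pushed through the Taylor
circular bandwidth rule). Overlap between two species is the coefficient
of overlapping Δ̂₄ ∈ [0, 1] (Δ̂₁ is also available), with a smoothed-
bootstrap percentile CI, and equality of the two distributions is tested
with Watson's two-sample U², read against the asymptotic critical-value
table or by permutation.

**Occupancy models.** Independent events become site × occasion detection
histories (six 10-day occasions per season, day 31 excluded; 1 / 0 / NA
coding). The single-season single-species model

    L_i = ψ_i ∏_j p_ij^{y_ij} (1 − p_ij)^{1 − y_ij} + (1 − ψ_i) · I(no detections)

is fit by maximum likelihood with logit-linked covariates (year, habitat,
altitude, slope; at most one categorical and one continuous term per
parameter, giving an 81-model candidate set), ranked by AICc, and
model-averaged over the ΔAICc < 2 competitive set. The two-species model
uses the ψBa/rBa parameterization (ψA, ψBA, ψBa, pA, pB, rA, rBA, rBa)
with the two classic constraint scenarios (ψBA = ψBa or not; pB = rBA =
rBa or not) and shared year/altitude detection offsets, and reports the
species interaction factor

    SIF (φ) = ψA·ψBA / (ψA·(ψA·ψBA + (1 − ψA)·ψBa)),

the ratio of joint occupancy to the product of the marginals: 1 means
independent site use, < 1 spatial segregation, > 1 aggregation.

Model fitting follows the scikit-learn estimator convention
(`SingleSeasonOccupancy`, `TwoSpeciesOccupancy`, `CircularKernelDensity`
with `fit()` and trailing-underscore fitted attributes); module-level
functions (`fit_single`, `fit_two`, `overlap_dhat4`, …) are thin wrappers.

## Worked example

```python
import sympatry as sy
from sympatry.diel import DielSample, times_to_radians, bootstrap_overlap, watson_two_sample

study = sy.simulate_study(sy.SimConfig(seed=1))          # 39 camera-years
events, deployments = study["events"], study["deployments"]
ind = sy.filter_independent(events, 30)

r = sy.compute_rai(ind, deployments, "deer", "summer", 2017)
print(f"deer summer 2017: RAI={r.rai:.2f} (SE {r.se:.2f}), "
      f"{r.n_events} events / {r.trap_nights} trap nights")

summer = ind[ind.timestamp.dt.month.isin([7, 8])]
deer  = DielSample("deer",  "summer", times_to_radians(summer[summer.species == "deer"].timestamp))
serow = DielSample("serow", "summer", times_to_radians(summer[summer.species == "serow"].timestamp))
ov = bootstrap_overlap(deer, serow, n_boot=1000, seed=1)
wt = watson_two_sample(deer, serow, n_perm=1000, seed=1)
print(f"Dhat4={ov.delta:.3f} CI [{ov.ci_low:.3f}, {ov.ci_high:.3f}]; "
      f"U2={wt.u2:.3f} {wt.p_bracket}")

ha = study["histories"]["summer"]["deer"]
hb = study["histories"]["summer"]["serow"]
fit = sy.TwoSpeciesOccupancy(psi_equal=True, det_equal=False,
                             detection_covariates=("year",), seed=1).fit(ha, hb)
print(f"AICc={fit.aicc_:.2f}  SIF = {fit.sif_:.2f} +/- {fit.sif_se_:.2f}")
```

prints

```
deer summer 2017: RAI=6.20 (SE 1.31), 50 events / 806 trap nights
Dhat4=0.839 CI [0.760, 0.953]; U2=0.286 <0.01
AICc=495.28  SIF = 1.00 +/- 0.00
```

Reading: deer were recorded about 6 independent times per 100 trap nights
in the 2017 summer; the two species' simulated activity curves overlap
strongly (Δ̂₄ ≈ 0.84) but differ significantly in shape (U², P < 0.01) —
the generator's deer are crepuscular while its serow are cathemeral; and
the two-species fit, constrained to no occupancy interaction (the
generator's truth), reports SIF = 1.00 ± 0.00, i.e. independent site use.

A `sympatry` console script exposes the same stages
(`simulate`, `filter-events`, `rai`, `diel-overlap`, `build-history`,
`occu-fit`, `occu-select`, `occu2-fit`, `pipeline`); `sympatry pipeline
--config cfg.yaml` runs everything end to end and writes per-stage CSV
artifacts plus a JSON manifest.

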