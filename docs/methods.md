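# Methods

## The problem

Earth-system models disagree strongly on how much soil carbon will be lost
as the climate warms. A large part of that disagreement traces to the
temperature sensitivity of the *effective soil-carbon turnover time*

    tau_s = C_s / R_h        [years],

the apparent whole-pool residence time of the top-metre soil carbon stock
C_s (kg C m⁻²) given the heterotrophic respiration flux R_h. Writing the
change in soil carbon as a litter-input term plus a turnover term,

    dC_s ≈ tau_s0 · dR_h  +  R_h0 · dtau_s,

this package computes and constrains only the turnover component

    dC_s,tau = R_h0 · dtau_s,

with R_h0 frozen at its reference-decade mean. The litter-input term is
deliberately out of scope.

## The spatial emergent constraint

The key assumption is a space-for-time substitution: the *spatial*
relationship between ln(tau_s) and near-surface air temperature T observed
across the present-day world carries information about the *temporal*
response of tau_s to warming. Concretely:

1. **Diagnose** per-cell tau_s for each model and for the observations over
   a reference decade (models 1995–2005, observations 2001–2010; per-second
   fluxes are converted with tau_s = C_s / (R_h · 86400 · 365)).
2. **Fit** an unweighted ordinary-least-squares quadratic p(T) to the
   per-cell (T, ln tau_s) scatter. The natural logarithm is used throughout
   so the fit inverts with exp.
3. **Warming levels.** For each model × scenario, the year a global warming
   level ΔT (e.g. 2 °C) is first reached is found from the 5-year centred
   rolling mean of global-mean temperature relative to the baseline-decade
   mean of the unsmoothed series; the spatial temperature field is averaged
   over the 11-year window centred there (−5…+5 inclusive).
4. **Reconstruct.** The *actual* dC_s,tau diagnoses dtau_s from the model's
   own evolving fields (annual tau_s averaged over each window); the
   *estimated* dC_s,tau replaces the temporal response with the spatial fit,
   dtau_s = exp(p(T_future)) − exp(p(T_hist)). Both are integrated to
   area-weighted global totals (PgC) over valid cells. Agreement between the
   two across an ensemble is the proof of concept.
5. **Constrain.** Each model's warming anomaly (future minus reference
   field, bilinearly regridded) is added to the observational temperature
   climatology, removing mean-state bias; pushing these pseudo-observational
   temperature pairs through the *observational* fit and R_h0 yields one
   observation-derived estimate x per model, summarised by its mean and
   sample standard deviation. The ensemble scatter (x = estimated,
   y = actual) is fitted by OLS, and the constrained posterior of y is the
   Gaussian integral

       P(y) = ∫ N(y; a + b·x, σ_f²(x)) · N(x; x_obs, s_obs²) dx,
       σ_f²(x) = s² (1 + 1/n + (x − x̄)² / (n·var(x))),

   with s² the residual variance on n−2 degrees of freedom — the standard
   least-squares emergent-constraint form. The prior is a Gaussian fit
   (sample mean/sd) to the raw ensemble y values.
6. **Effective q10.** A single-pool q10 law gives
   dC_s,tau = C_s0 [exp(−0.1 ln(q10) ΔT) − 1]; inverting it maps a
   constrained dC_s,tau at warming ΔT to an aggregate global sensitivity
   (q10 = 2 ⇔ ≈ 7 %/°C loss). Uncertainty is propagated by inverse-CDF
   sampling of the constrained density (10⁵ draws, fixed seed). The
   effective q10 is a global diagnostic and has no direct mapping onto the
   spatial-fit coefficients.

## Numerical choices

- **Grids and totals.** Cell areas are exact spherical quadrilaterals,
  A = R² Δλ (sin φ_top − sin φ_bot), R = 6 371 000 m; a uniform
  1 kg C m⁻² field integrates to ≈ 510.06 PgC. Masked cells are excluded
  from every aggregate.
- **NetCDF dialect.** Files are CF-style NetCDF3 (time, lat, lon) with the
  time coordinate in decimal years, read calendar-agnostically by grouping
  slices on floor(time); monthly slices are averaged unweighted to calendar
  years (the error of unweighted month lengths is negligible at decadal
  averaging). Bounds absent from a file are reconstructed as center
  midpoints with latitude edges clamped to ±90°.
- **Regridding** is bilinear (nearest-neighbour available), periodic in
  longitude, with mask-aware weight renormalisation: a target cell is
  masked only where its entire source support is masked; constant fields
  are preserved exactly. Poleward of the source centers the edge value is
  used.
- **Masking.** Cells with R_h below 10⁻⁴ kg C m⁻² yr⁻¹ (deserts, ice) or
  C_s ≤ 0 have unbounded or undefined turnover and are masked rather than
  raising; the fit reports n_cells so the sensitivity of any result to the
  mask is visible.
- **Fit degeneracies.** Fewer than 3 jointly valid cells, or zero
  temperature spread, raise immediately. Cells are unweighted by default
  (one grid cell, one point, the scatter-plot convention); area weighting
  is available as an option.
- **Warming-year detection** uses a 1 ppb °C slack so exact analytic
  crossings are not missed to floating-point dust. A level never reached
  raises a dedicated signal and the run is skipped (and listed) rather than
  failing the ensemble.
- **Posterior quadrature.** The y grid spans both the prior and constrained
  densities by ≥ 6 combined standard deviations (x grid ±8 s_obs); the
  conditional sd is floored at twice the y spacing so near-zero residual
  variance stays resolvable; a normalisation loss above 10⁻³ raises with
  advice to widen the grid. A vanishing combined spread returns an exact
  point mass. Moments are computed by trapezoidal integration and are
  stable to < 0.5 % under 2× grid refinement.

## The synthetic ensemble

Real CMIP archives and the observational products (soil-carbon inventories,
data-assimilated respiration, reanalysis temperature) are deliberately not
downloaded; a generator produces a pseudo-ESM world with the statistical
structure the method relies on, and with exact known truth:

- **Climatology:** T(lat) = 28 − 0.6·|lat| °C + N(0, 2 °C), clipped to
  [−25, 32] °C — the observed equator-to-pole contrast, so warm-region
  turnover is fast (~7 yr) and cold regions hold carbon for centuries.
- **Per-model truth relation:** each pseudo-model owns coefficients
  (c2, c1, c0) near the central relation (tau ≈ 7 yr at 25 °C, ≈ 150 yr at
  −10 °C) and *obeys them by construction*: per cell,
  ln tau_s = p_true(T) + η with η a frozen cell-level residual
  (sd 0.6 ln-years by default — soil properties, not weather);
  R_h = r₀·exp(0.05·T)·δ with frozen lognormal noise δ (sigma 0.3), floored;
  C_s = tau_s · R_h. Both η and δ are mean-one in linear space
  (lognormal with μ = −σ²/2), so the expected stock at a given temperature
  is exactly exp(p_true(T))·R_h and the per-model analytic truth
  R_h0·(exp p_true(T + ΔT_pattern) − exp p_true(T)), integrated over land,
  needs no noise correction.
- **Warming:** three linear scenario ramps (1.4 / 2.8 / 5.0 °C at 2100,
  before a per-model climate-sensitivity factor of 0.8–1.3), polar-amplified
  by 1 + a·max(0, (|lat| − 40)/50) with a ∈ [0.5, 1.5], plus interannual
  noise (sd 0.15 °C) on the global mean — enough structure for the rolling
  mean and warming-level extraction to do real work.
- **Ensemble:** sixteen models (the CMIP5+CMIP6 ensemble size) spanning
  slope, intercept, respiration scale, sensitivity and polar amplification;
  their 2 °C spread is of the same order as the ensemble mean.
  The 46×72 (≈ 4°×5°) default grid keeps every stage at seconds scale while
  leaving ~1000 land cells for stable fits.
- **Pseudo-observations** use the central (observed-world) relation — which
  no ensemble member matches exactly — with 10 % multiplicative
  observational noise on C_s and R_h and a continental blob mask (~30 %
  land) defined as a continuous function of (lat, lon), so different grids
  see the same continents.

Everything is bit-reproducible from (config, seed); a single `--seed`
drives every stream.

### What the generator does not emulate

Soil-moisture and soil-type covariates of the ln tau scatter, permafrost
and depth structure, disturbance fluxes, real CMIP model identities, ocean
dynamics and internal variability patterns, and curvilinear model grids.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline and the statistical machinery under the stated
generative assumptions — not that the real-world constraint is unbiased
with respect to processes the generator omits.

## Design choices where the design was open

- Model fields are totalled on their native grids (per-model global sums
  need no common grid); only temperature anomalies are regridded, onto the
  observational grid.
- Historical and scenario series are one concatenated run per model ×
  scenario, smoothed as a whole.
- The "actual" future tau averages annual tau over the window; dividing
  window-mean C_s by window-mean R_h is available behind a flag
  (`tau_from_mean_state`) for sensitivity checks.
- All scenarios of a model that reach a level contribute separate scatter
  points; generational subsetting is a caller-side filter on model ids.
- NPP may stand in for R_h under the steady-state approximation; the
  pipeline treats it identically (flag it in your own provenance).
- The CLI exposes each stage (`simulate`, `diagnose`, `fit`,
  `warming-level`, `reconstruct`, `constrain`, `q10`, `run`) as a thin
  wrapper; the library functions are the primary interface.

## Known limitations

- r² on the default synthetic ensemble (~0.99) is higher than for real
  model archives (~0.87–0.90): pseudo-models obey their own quadratics by
  construction, while real models harbour processes the spatial fit cannot
  see. The noise-free configuration reaches the exact 1:1 limit.
- The OLS emergent regression ignores errors in x and model
  non-independence; the observational x distribution is Gaussian by fiat.
- Warming-level detection is quantised to whole years; the first-crossing
  rule can overshoot the nominal level by a fraction of a year's warming.
- Only bilinear/nearest regridding is provided (not conservative), adequate
  for smooth temperature anomalies but not for flux conservation.
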