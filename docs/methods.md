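# Methods

## Model

Receptors occupy three pools: cell surface (`r_s`), internal (`r_i`,
lumping endosomal, lysosomal and nuclear compartments) and free shed
ectodomain in the medium (`r_f`). Mass-action fluxes connect them —
synthesis `P_syn` (molecules cell⁻¹ min⁻¹, delivered to the surface),
endocytosis `k_end`, recycling `k_rec`, internal degradation `k_deg` and
surface shedding `k_shed` (all min⁻¹):

    dr_i/dt = k_end r_s − (k_rec + k_deg) r_i
    dr_s/dt = P_syn + k_rec r_i − (k_end + k_shed) r_s
    dr_f/dt = k_shed r_s

These rates are semi-mechanistic: each lumps ligand binding, adaptor
recruitment and related machinery into a single first-order step, which
is the resolution the data support. Time is minutes everywhere; the
24-h end-point horizon is 1440 min.

The system is linear, so `rtktraffic.model_core` solves it in closed form:
eigen-decomposition of the 2×2 `(r_i, r_s)` block (its discriminant
`(a11−a22)² + 4 k_end k_rec` is non-negative, so eigenvalues are real)
plus analytic quadrature of `r_s` for `r_f`. Degenerate spectra and the
no-fixed-point case fall back to an augmented 4×4 matrix exponential,
which is exact for any rate combination. The closed form is validated in
the test suite against an independent high-order Runge–Kutta integration
at relative tolerance 1e-6 (with an absolute floor of 1e-4 of the
trajectory scale, where the RK oracle's own accumulated error dominates
for components that decay through five or more decades). Determinism and
speed (~tens of microseconds per likelihood evaluation) are what make
direct MCMC over the ODE model practical.

Pulse-chase (surface-biotinylation) experiments follow only receptor
labelled at t = 0, so the chased pool obeys the homogeneous system with
`P_syn = 0`; total label is non-increasing and the dynamics are invariant
to the label scale, which is why time-course data can be normalized to
the first time point without loss.

### Steady state and end-point initial conditions

For positive rates the cellular pools have the fixed point
`r_i*/r_s* = k_end/(k_rec + k_deg)` and
`r_s* = P_syn / (k_end + k_shed − k_end k_rec/(k_rec + k_deg))`; `r_f`
grows without bound (the medium is an absorbing pool), reported as the
steady shedding rate `k_shed r_s*`. The 24-h end-point simulation starts
from an initial total `r_t,0` split between surface and internal using
the steady-state fraction implied by the candidate parameters — cells are
assumed near steady state when treatment begins; the observed data do not
constrain the split directly, and the steady split is the only
parameter-consistent choice that needs no extra unknowns. (An
alternative split from the surface-fraction prior would add a nuisance
parameter for little identifiability gain.)

## Quantification

Bead-ELISA readouts (MFU) are calibrated by five-parameter logistic
regression, `y = d + (a − d)/(1 + (x/c)^b)^g` with `g > 0`, fit by
least squares from asymptote/midpoint initial guesses with ten jittered
restarts. Analyte mass converts to receptors per cell as

    r = m_r · dil · prot_cell · N_A / (c_prot · MW · v_lys)

with masses in pg (an explicit pg→g factor keeps the mole count
correct) and a per-cell protein content of 300 pg/cell; the worked
default (1 pg analyte, 3 µg total protein, 100 kDa standard) gives
602.2 molecules/cell. The LLOQ is the lowest standard whose mean readout
exceeds 5× the mean blank and whose back-fit concentration is within 20%
of truth; well counts and volumes needed to express it as a molecular
flux (molecules cell⁻¹ h⁻¹) are configuration inputs. Batches are
aligned by a single multiplicative offset, in-experiment control median →
absolute reference, applied exactly once.

## Priors

All kinetic priors act on log10 parameters (matching the optimization
bounds: [−6, 0] for the four rates, [0, 5] for log10 `P_syn`).

* **Literature anchors** (`P_syn`: 10², rates: 10⁻²) with σ_p = 2
  decades. The source description of the prior spread ("10²") is
  ambiguous between the raw and log scale; two decades is the reading
  that yields a proper, wide-but-informative prior, and the literal raw
  value remains available by configuration.
* **Shedding prior from data.** If surface levels are roughly constant
  over the end-point window, integrating the shedding equation gives
  `k_shed ≈ r_f/(r_t f_s Δt)`. Drawing `f_s` (truncated normal, mean
  0.85, sd 0.1, bounds [0, 1]) and `r_f`, `r_t` (normal, replicate mean
  and sd) 10,000 times yields a log10-normal prior. When the treatment
  changes abundances substantially within the window this estimate is
  biased toward the end-state surface level — one reason the prior is a
  prior and not an estimator.
* **Censored analytes.** When the supernatant never clears the LLOQ,
  the hourly flux is modelled Uniform(1, LLOQ) molecules cell⁻¹ h⁻¹,
  converted to `k_shed = flux/(60 r_t f_s)`; the sampled min/max log10
  values bound a uniform prior.
* **Surface fraction.** The same truncated normal (0.85 ± 0.1 on [0, 1])
  is applied to the model's steady-state surface fraction
  `r_s*/(r_s* + r_i*)` — the only parameter-dependent surface-fraction
  quantity in the model.
* **Initial conditions.** End-point `r_t,0`: truncated normal at the
  control condition's replicate mean and sd (treatments start from the
  control state); `r_f,0 = 0` (media washout). Time-course initial
  internal/total label: truncated normals centred on the first measured
  time point with a deliberately loose sd of 10 normalized units,
  constrained to `r_t(0) ≥ r_i(0) ≥ 0`.
* **Treatment updates.** After the control fit, each treatment's kinetic
  prior becomes normal at the control posterior mean with twice the
  posterior sd (uniform kinds keep their bounds).

## Likelihood

Log10-transformed observations are modelled as Gaussian around the
log10 model prediction with one noise sd per experiment type (end-point
lysate, end-point supernatant, time-course total, time-course internal).
Each σ_e is the median over all conditions of the within-replicate-group
sd of log10 values, frozen before fitting. Censored (below-LLOQ)
supernatant replicates contribute nothing while the model predicts a
sub-LLOQ signal and a one-sided squared penalty when it predicts a
quantifiable one.

## Inference

Fitting one condition is two-stage:

1. **Global search.** Latin-hypercube start sites (default 100; scaled
   studies use 24) over the kinetic box, each polished by generalized
   pattern search (opportunistic coordinate polling, mesh ×2 on success,
   ×0.5 on failure, termination at mesh < 1e-6 of the per-dimension
   range or an iteration cap). The best optimum over starts (ties break
   by first-found) seeds the sampler.
2. **Adaptive Metropolis.** Four chains start from N(optimum, (5% CV)²)
   draws. Proposals are N(θ, C0·I) with C0 = 0.01 for the first
   t0 = 100 steps; afterwards N(θ, s_d (Cov(θ_0..t−1) + ε I)) with
   s_d = 0.2, ε = 1e-20 and a recursively updated history covariance.
   Two standard safeguards keep the adaptation out of known failure
   modes: a 5% mixture weight on the fixed C0 kernel, and a diminishing
   Robbins–Monro adaptation of a global log-scale toward an acceptance
   rate of 0.234 (both active only after t0, so the pre-onset proposal
   covariance is exactly C0·I). Without them, chains whose history
   covariance reflects a long uphill approach to the mode can reject
   essentially forever at realistic chain lengths. The default run is
   100,000 iterations with a 20,000-step burn-in; scaled-down studies in
   the test suite use 20,000/4,000.

Nuisance initial conditions are sampled jointly with the kinetics by
default (`init_mode="sampled"`); the end-point `r_t,0` coordinate is
parameterised as a ratio to its prior mean so every sampled coordinate
is O(1) under the fixed initial proposal scale. A `fixed` mode pins all
initial conditions at data means (note the time-course data means are
t = 5 values used as t = 0 states, a small deliberate approximation).

Convergence is monitored by the Gelman–Rubin potential scale reduction,
`R̂ = sqrt(((n−1)/n · W + B/n)/W)`, with R̂ < 1.1 as the convergence
call (the threshold is a convention, not a spec of the sampler). At the
scaled-down chain lengths some strongly correlated coordinates
(notably `P_syn`–`k_deg`–`r_t,0`) can retain R̂ above 1.1; summaries
carry the flag.

## Downstream analysis

* **Attribution.** Posterior kinetic samples are reduced to means of the
  log10 values, back-transformed (the sampled space; raw-scale means are
  available). Each treated parameter is substituted alone into the
  control vector, the 24-h lysate re-simulated, and the ratio to the
  control simulation reported; substituting all five reproduces the
  treated simulation exactly (composition identity).
* **Predictive envelopes.** 10% of post-burn-in steps are resampled as
  whole vectors — never coordinate-wise, preserving posterior
  correlations — and re-simulated; min–max plus 2.5/97.5% quantiles are
  reported per observable.
* **Overlap.** Control-vs-treated parameter movement is scored by
  pairing random posterior draws and taking the smaller tail fraction of
  the difference distribution (0.5 = indistinguishable, 0 = separated).
* **PCA.** Rows are cell line × treatment; columns receptor × parameter,
  holding either posterior-mean log10 parameters or predicted per-
  parameter lysate fold changes. Cells whose overlap with control
  exceeds 25% are reset to the control mean (or fold change 1);
  a cutoff of 0 disables the rule. Columns are z-scored within each
  cell line's rows (sample sd, ddof = 1; zero-variance columns map to 0
  to stay PCA-ready), blocks concatenated, and a column-centred SVD
  yields scores and loadings with a deterministic sign convention
  (largest-magnitude loading positive).

## Synthetic study design

The generator emulates the study's design with four receptor analogs
whose control kinetics give abundances of 2×10⁴–5×10⁵ molecules/cell,
steady surface fractions near 0.85, and shedding from ~0.4%/h of lysate
(axl-like) through ~4%/h (met-like) down to sub-LLOQ (her2-like, whose
supernatant is censored at the 89 molecules cell⁻¹ h⁻¹ LLOQ).
Treatment presets scale rates multiplicatively: EGF-like (endocytosis
×3 for the EGFR/Her2 analogs), metalloprotease-inhibitor-like (shedding
×0.2 everywhere), Mek-inhibitor-like (synthesis ×2.5, degradation ×0.6,
endocytosis ×0.7 for the Axl/Her2 analogs) and Erk-inhibitor-like
(synthesis ×2 only).

End-point data are 12 replicates of 24-h lysate and supernatant
simulated from the control steady state under treated kinetics;
time-course data are 18 replicates per time point (5, 20, 45, 75,
90 min) of pulse-chase total and internal label, normalized to the mean
total at 5 min. Noise is log-normal (normal on log10 with sds 0.10,
0.15, 0.05, 0.08 for lysate/supernatant/total/internal — roughly 12–40%
CV, typical of replicated bead-ELISA and biotinylation measurements),
matching the likelihood's assumption; a raw-additive mode exists for
robustness checks. The generator is a pure function of (scenario, seed).

What the generator does not emulate: day/plate replicate hierarchy,
plate effects, dilution selection, or any imaging readout. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under a well-specified noise model at the study's sample
sizes — not robustness to the structured, non-log-normal variability of
real assays.

## Problem sizes and numerical choices

The test suite and acceptance script run scaled-down studies — 24
latin-hypercube starts and 4 × 20,000-step chains (4,000 burn-in) for
recovery, 4 × 8,000 (2,000) inside the end-to-end pipeline — sizes at
which the posterior geometry is already representative while a full fit
takes tens of seconds. Parameter recovery is scored on `P_syn`,
`k_deg`, `k_end`, `k_shed`; recycling (`k_rec`) is reported but held to
a wider band, as the data constrain mainly `k_rec + k_deg` and the
internal/total label split. All randomness flows through seeded numpy
generators; a config + seed pair reproduces every pipeline artifact bit
for bit. Degenerate inputs (zero rates, absent fixed points, constant
standard curves, zero-variance posteriors) raise explicit errors rather
than propagating NaNs.

## Known limitations

* The shedding-prior approximation assumes near-constant surface levels
  over the end-point window; strong treatments violate it and shift the
  prior, which the likelihood must then overcome.
* `k_deg` and `k_rec` enter the internal-pool equation only as the sum
  `k_rec + k_deg`; they separate solely through total-mass loss. For
  some noise realizations the posterior splits between the generating
  mode and a compensating low-degradation/fast-recycling mode of equal
  posterior height, leaving `k_deg` with a decade-wide, skewed
  posterior. Credible intervals remain calibrated (they cover truth);
  point estimates of `k_deg` should be read together with their
  interval, and `k_rec` is prior-dominated outright.
* At scaled-down chain lengths the sampler can leave R̂ > 1.1 on
  correlated coordinates; production fits should use the full
  100,000-step chains.
* The 5PL fitter assumes monotone curves within the standard range;
  hook-effect (prozone) artifacts are out of scope.
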