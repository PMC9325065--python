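# Methods

This note documents the models, numerical choices and known limitations of
`shootflux`. It is written for users who need to judge what the pipeline
assumes and what passing its tests does and does not demonstrate.

## Closure model and trimming

A closure is the 7–10 min interval during which a shoot chamber is sealed
and its headspace recirculates through the analyser at ~1 Hz. The first
seconds mix the headspace and the last seconds can be corrupted by leaks or
clock errors, so flux fitting uses a trimmed half-open window
[t_start, t_end) in seconds from closure start.

Trimming is algorithmic rather than graphical so that it is reproducible:

1. a fixed deadband (default 30 s) is removed from the start;
2. a provisional line is fitted to the corrected CH₄ channel by
   least-trimmed squares (Theil–Sen start, then iterated OLS on the 60% of
   samples nearest the line, ≤10 iterations), which locks onto the dominant
   stable segment even when a third of the closure is contaminated;
3. leading and trailing runs whose rolling median absolute residual
   (5-sample window) exceeds k·(1.4826·MAD) of the kept residuals (default
   k = 4) are cut, and steps 2–3 repeat until the window is stable (≤10
   passes).

The window only ever shrinks and the operation is idempotent. Against an
exhaustive two-segment changepoint fit on simulated slope breaks, the
trimmed end lands within a few sampling intervals of the break. A closure
whose trimmed span falls below 120 s is discarded.

Quality control then labels (never raises): discard when (i) the trimmed
span is under 120 s or has fewer than 20 samples, (ii) the robust residual
SD of the CH₄ line exceeds a threshold (default 0.0025 ppm, ~5× the default
analyser noise), or (iii) the middle-third residual mean deviates from the
outer thirds by more than 6 standard errors (curvature/drift). Thresholds
are configurable; the reason is recorded per closure.

## Water-vapour interference

The analyser's internal water correction leaves a residual linear
cross-talk: reported dry CH₄ shifts by *f* ppm per ppm H₂O (default
−9.122 × 10⁻⁷). The correction is applied pointwise *before* trimming and
QC, because the H₂O trajectory is curved and would otherwise masquerade as
instability in the CH₄ channel. `estimate_f` calibrates *f* from
water-injection experiments as the mean of per-replicate OLS slopes with a
t-based 95% CI on that mean; a pooled-regression mode is available and the
mode used is recorded in the calibration metadata, since either reading of
"replicated six times" is defensible. Each replicate must span ≥5000 ppm of
H₂O or the slope is unidentifiable and the function raises.

## Flux computation

The internal slope unit is mol-fraction s⁻¹ (ppm × 10⁻⁶), which closes the
unit chain in F = dC/dt · M · pV/(RT) · 3600 given M in ng mol⁻¹ (CH₄) or
mg mol⁻¹ (CO₂). The sample temperature is the mean over the trim window
(an instantaneous reading is not better defined for a 1 Hz stream) and must
lie in 250–330 K. CH₄ uses the linear model and CO₂ the exponential model;
a switch allows exponential CH₄ for sensitivity studies.

The exponential fit keeps time on the closure clock (t = 0 at sealing), so
its initial slope estimates the undisturbed uptake at closure start rather
than at the trim start — with a 30 s deadband and k ≈ 0.004 s⁻¹ the
difference is ~12%, so this choice matters. Initialisation is C₀ from the
first sample, C_lim from the last, k from a log-linearised decrement;
restarts at 10k and k/10; if k is unidentifiable the fit falls back to the
linear slope with `converged=False`. Fits are unconstrained in sign: uptake
versus emission is carried by the sign of (C₀ − C_lim).

## Background and detection limits

Blank closures are tested for sensitivity to global radiation, air
temperature and time by separate OLS fits; the background model is the
radiation regression when that slope's two-sided t-test is significant at
α = 0.05, otherwise the campaign mean. Subtraction happens on the chamber
(ng h⁻¹) scale before dry-weight normalization, so differences between
shoots measured under equal radiation are preserved.

The detection limit per chamber closure is 3 × the sample SD (n−1) of the
blank apparent fluxes after their own H₂O correction but without background
subtraction. Dividing by the species' average shoot dry weight gives the
per-measurement limit; dividing further by √n (median closures per 14-day
period) gives the per-period limit. Full precision is carried internally;
reports round per-measurement limits to three significant figures and
per-period limits to two decimals. Fluxes below the per-measurement limit
are flagged, never deleted.

## Phenology and biomass

Needle mass in the chamber is m(t) = m_Y1 + rel(t)·m_Y0,final. Relative
growth rel(t) is measured shoot elongation (normalised by final length,
linearly interpolated between weekly observations) where observations
exist, otherwise a two-parameter logistic in cumulative growing degree days
above 5 °C — 1/(1 + e^(−s(GDD − g₅₀))), rescaled to equal exactly 1 at
campaign end, with defaults g₅₀ = 150 °C·day and s = 0.03 (°C·day)⁻¹. The
logistic is the minimal monotone S-curve for elongation in thermal time;
the cited elongation literature does not pin down a functional form, so the
parameters are exposed in configuration and `validate_growth_model` reports
RMSE and maximum deviation against measured curves. Daily mean temperature
is the calendar-day mean of the meteorological series. Fv/Fm is
(F_m − F_0)/F_m, the universal definition; inputs with F₀ > F_m are
rejected.

## Driver statistics

All regressions on repeated shoot measurements are random-intercept linear
mixed models (one intercept per tree, REML, statsmodels). Fixed-effect
p-values are Wald t with df = n_obs − p − n_groups — close to the normal
reference at campaign sizes but less liberal in small strata; under null
simulations all procedures hold their type-I error within Monte-Carlo slack
of 5%. A model with a single tree reduces exactly to OLS (flagged); a zero
intercept-variance estimate is reported as converged-but-singular; if the
optimiser fails on all of L-BFGS/CG, Powell and Nelder–Mead the OLS
solution is reported with a flag.

Period comparisons use cell-means coding for consecutive half-open 14-day
bins anchored at the first measurement date, all pairwise contrasts tested
with the studentized-range (Tukey) adjustment, and a compact letter display
computed as the maximal cliques of the not-different graph. The
shoot-versus-blank comparison is a Welch t-test on raw chamber-scale
(ng h⁻¹) fluxes, uncorrected for background — the variances of shoot and
blank chambers clearly differ, and comparing uncorrected fluxes against the
blank is the comparison that subtraction would otherwise make circular;
this convention is recorded in the analysis metadata.

The PAR split places rows with PAR exactly 500 µmol m⁻² s⁻¹ in both
strata, matching the overlapping ≤/≥ convention of the design it follows.
The temperature-bin analysis cuts air temperature at 0/5/10/15/20 °C
(outside values clipped into the end bins; bins under 5 rows merged into
their neighbour, noted in the output), codes the bin factor with
reverse-Helmert contrasts (level j versus the mean of colder levels;
columns orthogonal, zero-sum) and fits PAR, bin and PAR×bin with the tree
intercept. Per-bin PAR slopes ± SE are linear combinations of the fixed
effects; the interaction contrasts directly test whether each bin's light
response exceeds the mean of the colder bins. Residual disentangling
regresses the residuals of flux~temperature on PAR and vice versa to
identify which collinear driver carries independent information.

## Synthetic campaigns

The generator emulates the measurement system the pipeline assumes, with
every dial settable and a single seed giving byte-identical file output:

- **Emission truth**: F = base + (a₀ + a₁·T)·PAR + u_tree, defaults
  base = 1 ng gDW⁻¹ h⁻¹, a₀ = 0.002, a₁ = 0.0002 — a PAR slope of 0.004 at
  10 °C rising with temperature, the structure the interaction analysis
  must detect; u_tree ~ N(0, 1 ng gDW⁻¹ h⁻¹) drawn once per campaign.
- **Background**: constant 11.76 ng h⁻¹ by default, or linear in global
  radiation (0.06 ng h⁻¹ per W m⁻² around 150 W m⁻²).
- **Closures** at 1 Hz: true CH₄ linear at the slope implied by inverting
  the flux equation (first-order relaxation toward ambient when
  leak_rate > 0; default 0); CO₂ exponential toward a light-dependent
  asymptote (Michaelis-type drawdown, half-saturation 300 µmol m⁻² s⁻¹);
  H₂O saturating toward a 16 000 ppm ceiling; the *reported* CH₄ adds
  f_true·H₂O(t) so the correction path is exercised; Gaussian noise last
  (defaults 0.0005 ppm CH₄, 0.3 ppm CO₂, 5 ppm H₂O at 1 s).
- **Weather**: clipped diel PAR sinusoid × seasonal ramp × per-day cloud
  attenuation; global radiation = PAR/2.1 µmol J⁻¹ with 2% sensor scatter
  (collinear, R² > 0.97); temperature = seasonal ramp + diel cycle +
  day-to-day noise + optional coupling to the cloud anomaly, which creates
  the PAR–temperature covariance the residual analysis untangles.
- **Schedule**: three measurement days a week, three rounds a day, a blank
  closure leading every round; pine shoots in every round, spruce in the
  first daily round. The first-year-style preset (36 days) lands within
  10% of the 181/53 pine/spruce closure counts of the campaign design it
  emulates.
- **Biomass**: pine shoots average ~23 g DW (Y1 21 g + Y0 4 g), spruce
  ~6 g, 15% CV between trees; Y0 mass follows the same GDD logistic the
  pipeline uses.

Sample temperature is held at ambient air temperature during closures:
radiative heating inside the sealed chamber is real but unquantified in
the system being emulated, so it is not simulated. Chamber leakage
defaults to zero for the same reason.

What the generator does *not* emulate — and therefore what passing tests
cannot certify about field data: analyser drift and 1/f noise (noise is
white), real blank-flux variability beyond fitting noise (the simulated
background is deterministic, so simulated detection limits are far lower
than field ones), needle-temperature decoupling from air temperature,
pressure fluctuations, and non-linear chamber artefacts. Round-trip
accuracy on synthetic campaigns demonstrates the correctness of the
inference chain, not the field accuracy of the instrument.

## Problem sizes and determinism

The default verification sizes are chosen to give stable Monte-Carlo
estimates at interactive runtimes: 200 closures for default-noise recovery
(standard ~23.6 g shoots, where per-closure noise is ~2–3% of a typical
flux; a 5 g spruce shoot in the same chamber has ~4× the relative error —
the biomass-to-volume effect that limits small-shoot campaigns), 500
six-replicate experiments for calibration coverage, 150–400 repeats for
type-I and power checks. All simulations derive their streams from a
single seed; identical configuration and seed reproduce results bit for
bit, including written files.

## Known limitations

- The trim algorithm assumes a single dominant stable segment; closures
  with two equally long stable regimes at different slopes will keep the
  first-fitted one.
- Mixed-model inference uses Wald t statistics, not Satterthwaite or
  Kenward–Roger df; with ≤4 trees the random-intercept variance itself is
  poorly constrained (often estimated at the zero boundary and flagged).
- The CO₂ exponential assumes a constant uptake regime over the closure;
  stomatal responses within the closure alias into k.
- Detection limits use the campaign-pooled blank SD; per-chamber
  backgrounds are not modelled.
- Calendar handling is timezone-naive; campaigns spanning DST changes
  should use a fixed offset in their timestamps.
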