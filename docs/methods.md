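# Methods

## The measurement and its model

A gas push–pull test (GPPT) probes in-situ microbial CH4 oxidation in a
termite mound without removing material. A gas mixture of laboratory air
spiked with ~900 µl l⁻¹ CH4 (the reactant) and ~0.1 l l⁻¹ argon (a
conservative tracer with near-identical transport) is injected into the
mound centre for 24 min at ~0.5 l min⁻¹, then extracted from the same
point for 36 min at the same rate. During extraction the recovered gas
is progressively diluted with mound air; because Ar is not consumed, the
tracer separates dilution from reaction, and any CH4 deficit *relative
to the tracer* measures oxidation.

The analysis works with relative concentrations
C\* = (C − C_bg)/(C_inj − C_bg) per species and with the **transformed
reaction time** t\* of each extracted parcel. Under a last-in-first-out
plug-flow reading of the push–pull cycle with equal flows, a parcel
extracted at elapsed extraction time t_e was injected at t_inj − t_e, so

    t*(t_e) = 2·t_e              for t_e ≤ t_inj,
    t*(t_e) = t_e + t_inj        afterwards,

i.e. residence time accrues twice as fast as extraction time until all
injected gas is notionally recovered. For first-order kinetics with
activity coefficient k (h⁻¹),

    ln( C*_CH4 / C*_Ar ) = −k · t*,

so k is estimated by ordinary least squares of the log-ratio on t\*
(`estimate_activity`). This relation is exact whatever the dilution
history — the tracer cancels it — which is the central robustness
property of the method.

Concentration dependence is resolved by sliding windows of three
consecutive tracer-matched samples (`segment_rates`): each window gives
a local activity k_local (negative slope of its three log-ratio points
against t\*) and a running-average concentration C̄ (mean of the three
dimensional CH4 values, µmol l⁻¹ via the ideal-gas conversion), hence a
volumetric rate R_ox = k_local·C̄. The Michaelis–Menten (MM) model

    R_ox = V_max · C / (K_m + C)

is fitted to the (C̄, R_ox) pairs by nonlinear least squares
(`fit_kinetics`) and compared against a linear null model with the
identical Gaussian-likelihood AIC, n·ln(RSS/n) + 2(p+1). When the
linear model wins, or the MM fit does not converge, no MM parameters
are reported. Pairs from several mounds can be pooled (`pooled_fit`),
excluding linear-behaviour mounds by default.

### Why the linear null goes through the origin

The no-saturation alternative to MM is first-order kinetics, R = k·C,
which has no intercept; the segment construction itself forces
R_ox → 0 as C̄ → 0. The default null is therefore proportionality
(1 parameter); an affine variant is available (`intercept=True`). With
an affine null both families have two parameters, the shared AIC
formula reduces to a pure RSS comparison, and model selection on
near-linear data degenerates to a coin flip between two ways of
absorbing noise.

### Per-segment activity

The local 3-point slope, not the global k, multiplies C̄. A single
global k would make R_ox strictly proportional to C̄ by construction
and the MM fit degenerate; the local slope is what carries the
concentration dependence. This is the one genuinely open reading of the
segment procedure, and the package resolves it this way.

## The synthetic-data generator

The study's raw GPPT timeseries are not public, so the generator
(`simulate_gppt`) reproduces the field protocol with known ground
truth: 1 Hz CH4 record over 24 min injection + 36 min extraction,
3 injection-phase and 10–12 extraction-phase discrete Ar samples
(evenly spaced, count drawn from {10, 11, 12} when not fixed), plus one
pre-injection background sample.

* **Dilution**: single-exponential mixing with mound air,
  D(t_e) = exp(−t_e/τ), τ = 600 s by default, leaving ~3% of injectate
  at pump-off — "diluted down to background levels" over the 36 min
  extraction. The inference never uses this functional form, only the
  simulated tracer, so the choice cannot bias recovery of k.
* **Kinetics**: `none`, `first_order(k)` (closed form
  C\*_CH4/C\*_Ar = e^(−k·t\*)), or `michaelis_menten(km, vmax)`. For MM
  the consumption acts on the *in-situ* (diluted, background-inclusive)
  concentration: d ln r/dt\* = −V_max/(K_m + C_meas(t_e)), integrated
  with classical RK4 on the 1 Hz grid. This is exactly the continuum
  model the segment estimator linearises, so simulator and estimator
  share one definition of (K_m, V_max); applying the reaction to the
  undiluted injectate instead would decouple the concentration at which
  the kinetics act from the concentration the analysis records, and
  parameter recovery would be meaningless.
* **Noise**: multiplicative lognormal per measurement — 1% relative for
  the 1 Hz CH4 analyser, 2% for the discrete GC Ar samples by default,
  typical of field spectrometer and GC-TCD precision.
* **Units**: mixing ratios convert to molar concentrations with the
  ideal-gas law at 1 atm and the configured temperature
  (0.0409 µmol l⁻¹ per µl l⁻¹ at 298.15 K; 900 µl l⁻¹ ≈ 36.8 ≈ "~40" µM).
* **Background air**: CH4 10 µl l⁻¹ (mound air is methane-enriched,
  order 2–100 µl l⁻¹), Ar 0.0093 l l⁻¹ (atmospheric).

What the generator does **not** emulate: spatial heterogeneity of the
mound (different gas paths see different communities), kinetic shifts
during the test (e.g. isozyme induction at high CH4), drift or
autocorrelated instrument error, and non-exponential dilution. Passing
recovery tests therefore demonstrate correctness of the inference chain
under its own assumptions, not field accuracy.

## Matching the 1 Hz record to discrete tracer samples

Each Ar sample is paired with the **median** of the CH4 readings within
±5 s (`match_window`, `agg` configurable). For an odd, symmetric window
over a monotone series the median is exactly the central reading, so
noise-free data incur no aggregation bias; under multiplicative
lognormal noise the median is unbiased in log space, which is the space
the regression uses. The arithmetic mean, by contrast, carries a
curvature bias of order (decay rate)²·Var(t)/2 (~10⁻⁵ relative here)
that contaminates machine-precision recovery checks.

## Known numerical properties and limitations

* **Window-discretisation bias of the MM parameters.** Within a
  two-spacing window the concentration falls by a factor ≈ e^0.6 under
  the default dilution, so the window-averaged activity exceeds
  V_max/(K_m + C̄) (Jensen's inequality) and mid-curve segments sit up
  to ~5% above the true curve. Fitted to noise-free data at
  (K_m, V_max) = (13.2, 55.4), both parameters come back ~8% high. The
  bias scales with (sample spacing/τ)² and is a property of the
  3-point-segment method at 10–12 tracer samples, not of the optimiser;
  it is well below the mound-to-mound spread the method is used to
  resolve.
* **Model selection power.** With n ≈ 10 segments the AIC hurdle for MM
  over the proportional null is an RSS ratio of e^(2/n) ≈ 1.2; truly
  unsaturated data (K_m ≫ C) are reported linear in roughly three
  quarters of noisy replicates, the rest selecting MM with K_m
  estimates spread far above the observed concentration range.
  Consumers should treat MM selection at small n as evidence, not
  proof, of saturation.
* **MM fit**: log-parameterised trust-region least squares (tolerance
  1e−8), start values K_m⁰ = median(C̄), V_max⁰ = 1.5·max(R_ox), up to
  5 deterministic jittered restarts; parameters confined to
  [1e−8, 1e6] in their natural units, and a solution on the upper bound
  (the K_m → ∞ degeneracy on proportional data) is declared
  non-converged. Standard errors are Gauss–Newton estimates
  delta-transformed to the natural scale.
* **MM integrator**: the single-parcel reaction uses the implicit
  integral K_m ln(C/C₀) + (C − C₀) = −V_max·t, solved by bracketed root
  finding (relative tolerance ≤ 1e−9); it matches the first-order
  closed form to <0.1% when K_m ≥ 10⁴·C.
* **Negative activity estimates** are reported with a
  `no_detectable_oxidation` flag, never truncated to zero, so
  downstream correlations remain unbiased.

## Abundance conversions

qPCR calibration curves are OLS fits of Cq on log10(copies); the
amplification efficiency is 10^(−1/slope) − 1 and curves are flagged
when efficiency ≤ 70% or r² ≤ 0.98. Sample copies per reaction are
10^((C̄q − intercept)/slope), scaled by dilution factor ×
(eluate/template volume) per gram extracted. Triplicate Cq values are
averaged arithmetically and flagged when their sd exceeds 0.5 cycles;
non-amplifying samples are reported as *below detection* at the limit
implied by the most dilute standard, not as zero. Cell numbers assume
2 *pmoA* copies per methanotroph cell and 4.2 16S rRNA gene copies per
bacterial cell (both configurable). Metagenomic marker fractions divide
each target gene's RPKM by the mean RPKM of 14 universal single-copy
ribosomal genes; the two-copies-per-genome correction applies to *pmoA*
only (*mmoX* is treated as single-copy). Cell-specific oxidation rates
divide a whole-mound rate (µmol h⁻¹) by the pmoA-derived cell
inventory, giving mol CH4 cell⁻¹ h⁻¹.

## Statistical layer

Regressions between kinetic parameters, gene abundances and mound
physical properties use the field conventions: square-root transform
for kinetic parameters, log10 for abundances (rows where a transform is
undefined are dropped and reported). After the initial OLS fit,
observations with Cook's distance above 4/n are removed and the model
refitted exactly once — a deterministic, auditable stand-in for visual
influence diagnostics. Backward stepwise elimination drops, at each
step, the term whose removal most lowers the AIC, stopping when no
removal lowers it. Group comparisons use Kruskal–Wallis followed by
Dunn's pairwise rank z tests with tie correction and Holm adjustment
(the adjustment is configurable; none is prescribed by the field
convention). The compact letter display assigns letters to the maximal
cliques of the non-significance graph, so two groups share a letter
exactly when their adjusted p ≥ α.

## Problem sizes used in the checks

The bundled verification runs use 20 simulated GPPTs for first-order
recovery, single noise-free and 2%-noise tests at (13.2, 55.4) for MM
recovery, 50 replicates for the model-selection rate, an 8-mound
population (K_m log-uniform in 5–30 µmol l⁻¹) for the pooled fit, a
14-marker synthetic metagenome at 77M reads, and 2000 replicates of
three groups of 10 for the rank-test calibration — sizes chosen to
match the field study's scale while keeping a full run in seconds on a
laptop.
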