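# Methods

This note documents the models and estimation procedures implemented in
`thylakoid_biophys`, the defaults of the synthetic-data generators, the
numerical choices made where the design was genuinely open, and the limits
of what the parameter-recovery tests demonstrate.

## Scope and conventions

The package covers the desk-side analysis chain of a thylakoid
anion-channel study: bilayer electrophysiology, ECS dark-interval
relaxation, PAM fluorescence, SANS repeat-distance fitting and psi-type CD
band amplitudes. Units are fixed package-wide (s, pA, mV, pS, mM, Å⁻¹, Å,
nm). Electrophysiology adopts the bilayer convention: voltages are cis-side
relative to trans and positive current is carried by cations moving
cis → trans; no mapping onto the lumen/stroma orientation of the channel in
its native membrane is asserted, since insertion orientation in a painted
bilayer is not controlled.

## Single-channel generator

Gating is a two-state (closed/open) continuous-time Markov chain per
channel, simulated exactly (Gillespie) and sampled onto the recording grid.
The voltage dependence sits entirely in the opening rate through a
Boltzmann factor,

    k_open(V) = k_open_0 · exp(z_gate · V / (RT/F)),   k_close = const,

the simplest form that reproduces a channel more active at positive than at
negative potentials. Chains start from their stationary distribution, so
sweeps are statistically homogeneous from the first sample. Openings are
substates (unitary current scaled by `substate_fraction`) with probability
`substate_prob`; `n_channels` independent copies superpose to emulate
cooperative-looking stacked openings. The unitary current is piecewise
ohmic, i(V) = γ(V)·(V − V_rev)/1000 with separate conductances on the two
branches; recording noise is additive Gaussian.

Defaults: γ⁺ = 96.1 pS, γ⁻ = 60.0 pS (the KCl values the recovery targets
use), V_rev = 0 in symmetric baths, k_open_0 = k_close = 50 s⁻¹ and
z_gate = 0.3. No kinetic rate constants are available for this channel, so
the rates are *placeholders, not estimates*: they were chosen once so that
the voltage asymmetry is visible (stationary open probability ≈ 0.38 at
−40 mV vs ≈ 0.72 at +80 mV) while both branches keep enough open-state
occupancy that a 60-s, 5-kHz sweep yields well-populated amplitude
histograms. Conclusions that depend on dwell-time structure (burst
analysis, flicker kinetics) are outside what this generator can support.

## Unitary currents, idealization, conductance

The amplitude histogram bins every sample at fixed width (default 0.1 pA);
counts conserve the sample number exactly. The unitary current is the
separation of the two dominant histogram modes, obtained by least-squares
fitting a two-Gaussian mixture to the binned counts. Initialization uses
the two highest smoothed-histogram peaks (ties broken toward larger
separation) and falls back to weighted 25th/75th percentiles when the
second mode is only a shoulder. A trace is declared to have *no open
events* when a single Gaussian describes the histogram essentially as well
as two (SSE ratio ≥ 0.7), when the minor component carries < 0.5% of the
mass, or when the fitted modes coincide within one bin; near-noiseless
histograms (≤ 5 occupied bins) short-circuit to the occupied bins
themselves. The returned value is *signed* (open mode minus closed mode,
open = farther from 0 pA) so that negative-branch regressions carry the
correct sign. With substates present the two dominant components still
capture the closed and full-open levels provided substate dwell mass stays
well below either; heavily substate-dominated records are not resolved.

Idealization is a half-amplitude threshold on the projection
r = (I − closed)/i_u (open at r > 1/2; with a substate fraction f, level
thresholds at f/2 and (1+f)/2), without digital filtering by default — an
optional moving-average prefilter exists but is off, keeping the default
rule exactly reproducible. Dwell segments tile the trace; open probability
counts substate time as open.

Slope conductance is a per-branch least-squares line through the reversal
point, γ = 1000·Σ(ΔV·i)/ΣΔV² (pS); the branch is chosen by the sign of
V − V_rev. A branch without data is reported unavailable rather than an
error, because published branch conductances are routinely one-sided. The
nitrate-style analysis fits a single slope across both branches
(`mode="single"`). Whether published conductances derive from I–V
regression or single-voltage amplitudes is generally unstated; regression
is the default here and single-voltage amplitudes remain accessible through
the unitary-current estimates themselves.

## GHK selectivity

The monovalent GHK voltage equation is used in its anion convention with
p = P_K/P_Cl:

    V_rev = (RT/F) · ln[(p·[K]_t + [Cl]_c) / (p·[K]_c + [Cl]_t)],

RT/F = 25.693 mV at 298.15 K. Its closed-form inverse,
p = ([Cl]_c − u·[Cl]_t)/(u·[K]_c − [K]_t) with u = exp(V_rev/(RT/F)),
is exact; the forward–inverse round trip is machine-precision over
p ∈ [0, 10] and the equation is strictly monotone in p for a fixed
asymmetric gradient. A symmetric bath makes p unidentifiable (error), and a
V_rev outside the window bounded by the Cl⁻ and K⁺ Nernst potentials is
rejected; the exactly-attainable boundary is tolerated to 1e-9 relative to
absorb float rounding. Concentrations are used as-is (no activity
coefficients), matching common practice at these ionic strengths.

For synthesizing I–V data the package also provides the GHK current
(constant-field flux) model; its zero crossing coincides analytically with
the voltage equation, which the tests verify numerically. The zero-current
potential of a *noisy* I–V curve is estimated by fitting the two-parameter
constant-field shape (overall scale and p) and taking its root
(`estimate_reversal_potential`, method `"ghk-shape"`): a local two-point
interpolation wastes most of the curve and, at 5% noise on 11 points,
leaves the inverted p with a standard deviation of ~0.09, versus ~0.03 for
the shape fit — near the information limit of such a curve. The recovery
pipeline additionally averages three replicate sweeps (matching the
triplicate design typical for this measurement), bringing the spread to
~0.02. Plain linear interpolation remains available for clean data.

## ECS dark-interval relaxation

The generator is phenomenological, not mechanistic: the dark baseline is 0;
illumination raises the signal to `s_light`; at light-off the signal
relaxes single-exponentially (τ = `tau_decay_ms`) toward an inverted
quasi-stable level `s_inv` with ECS_t = s_light − s_inv and
f_ΔΨ = s_light/ECS_t; single-turnover flashes are instantaneous steps of
`ecs_st_amp` decaying with the same τ. ECS_t derives from
`s_light/f_dpsi`; passing `ecs_t` explicitly permits f_ΔΨ = 0 (PMF stored
entirely as ΔpH — the phenotype of strong channel overexpression). Real ECS
decays are multi-phasic and contaminated by zeaxanthin/qE absorbance
changes; neither is modelled, so recovery tests validate the estimator
arithmetic, not instrument realism.

Analysis reduces the dark-interval-relaxation method to three level
estimates: S_light = mean of the last 20 ms of light before light-off
(half-open window — the sample at light-off belongs to the relaxation),
S_inv = mean of the last 50 ms of the 600-ms interval, S_base = mean of the
annotated dark-baseline window. The interval must be ≥ 300 ms so the
inverted level has settled (with the default τ = 25 ms the residual
transient at the read-out window is e⁻²² ≈ 3·10⁻¹⁰ of ECS_t, i.e.
recovery is exact to float noise). The published protocols state the 600-ms
interval and the 100-ms fit window but not the level-estimation windows;
the 20/50/10-ms defaults here are explicit, configurable choices. f_ΔΨ is
clipped to [0, 1] with a warning rather than raising, because a missing
undershoot (apparent f_ΔΨ > 1) is a real phenotype signature (ECS_t
underestimation), not a pipeline failure; grazing the boundary within 1e-9
is clipped silently. ECS_t ≤ 0 raises a *no PMF signal* error.

g_H⁺: nonlinear least squares of S(t) = S_∞ + ΔS·e^(−t/τ) over the first
100 ms after light-off (≥ 20 samples required), initialized from the
last-5-ms mean (S_∞) and a log-linear fit of the positive residual (τ);
g_H⁺ = 1/τ. The fit does not subtract the inverted level beforehand — S_∞
is free, which absorbs it. Non-decaying segments (ΔS ≤ 0 or τ ≤ 0) raise a
*no decay* error. Monte-Carlo at 2% noise recovers τ within ±5% in ≥ 95 of
100 runs. Flash normalization multiplies each ECS_t by max(ECS_ST)/ECS_ST,
leaving the largest-flash measurement unchanged; it is idempotent after
equalization and invariant under common rescaling of the flash amplitudes.

## PAM fluorescence

The generator inverts the parameter definitions: at each pulse
F_m′ = F_m/(1 + NPQ_target) and the preceding steady state
F = F_m′·(1 − Φ_target), with a 0.3-s saturating pulse and piecewise-
constant steady levels. Analysis extracts F_m′ as the maximum within an
800-ms window centred on the pulse and F as the mean of the 200 ms before
that window; the published instruments are named in such studies but not
the extraction windows, so these defaults are deliberate and configurable.
Analysis ∘ generation is the identity on the (NPQ, Φ_II) courses for
noiseless traces to < 1e-9 relative; both parameters are invariant under
joint rescaling of all fluorescence values. Pulses must be ≥ 1.3 s apart
for the default windows (enforced at generation; overlapping analysis
windows raise). The dark F_m is carried per trace — batch F_m values are
the caller's responsibility.

## SANS

The lamellar model is constant + power-law + *amplitude-form* Gaussian
(width c as a standard deviation): the area-form normalization cannot be
distinguished by fitting anyway (it rescales B), so the amplitude form is
used and documented. Replicate curves are averaged pointwise on a shared q
grid (tolerance 1e-9); with ≥ 3 replicates the uncertainty is the sd of the
mean, with 2 it propagates per-point sigmas when present.

The six-parameter fit is weighted (1/σ²) when uncertainties exist.
Initialization is a coarse grid over the nonlinear parameters — p over
{1…7}, q\* over every second window point plus a median-filter-background
peak candidate, c geometric between span/40 and span/4 — solving the linear
(I₀, A, B) subproblem exactly at each node and seeding lmfit from the
lowest-SSE node (ties toward larger B); a single-start fit of
power-law-plus-peak models is prone to local optima that this scan avoids.
The polished fit recovers all six parameters of a noiseless generated curve
to < 1e-4 relative inside the leaf window (0.0151–0.0380 Å⁻¹); at 1% noise
q\* is recovered to < 0.5%, and at 2% noise to within 2% in ≥ 45/50 seeds.
A fitted peak amplitude ≤ 0 within 2 standard errors (or ≤ 1e-10 of the
intensity scale) raises *no Bragg peak*. RD = 2π/q\* with q\* constrained
inside the fit window. Whether published fits of this kind are weighted is
typically unstated; weighting by counting σ is the defensible default.

## Psi-type CD

Spectra are normalized by the red-most absorption peak value (factor
recorded and composable). Band amplitudes are two-point differences,
CD(band) − CD(reference), with linear interpolation on the 400–800 nm grid
and the standard pairs 505/550, 675/600, 690/750 nm; a local-extremum
search around the nominal band positions is deliberately not the default —
the two-point rule is deterministic and testable. Baseline handling beyond
a constant offset (which the two-point difference cancels by construction)
is out of scope.

## Reproducibility and I/O

All randomness flows from one integer seed through
`numpy.random.default_rng`; multi-trace generators and the pipeline runner
spawn independent child streams with `SeedSequence`, so fixed seeds give
bit-identical outputs. Files are tab-separated text with a `#` header
(format tag, kind, one sorted-key JSON metadata line, column names) and
%.17g floats, which round-trip float64 exactly: writes are
byte-deterministic and read(write(x)) = x. The pipeline runner validates
configurations strictly (unknown keys rejected by name) and records
provenance (stage parameters, child seed, input files, timing, package
version) next to every derived quantity.

## Problem sizes of the recovery targets

The headline recovery runs use 60-s sweeps at 5 kHz (3·10⁵ samples per
voltage; three voltages per KCl branch, six for KNO₃) with 0.8 pA (KCl) or
0.5 pA (KNO₃) noise, and 11-voltage I–V curves in triplicate at 5% noise
for the selectivity ratio — sizes at which the estimator spreads
(±2% on unitary currents, ±0.02 on the permeability ratio) sit comfortably
inside the tolerances being checked, while the whole suite stays a
desk-scale computation.

## Known limitations

* Gating rates, substate statistics and multi-channel cooperativity in the
  generator are plausibility placeholders; only the conductances and the
  selectivity ratio are anchored to published values.
* The ECS model is single-exponential with a stable inverted level; slow
  relaxation of that level within the interval and multi-phasic decays are
  ignored.
* No hidden-Markov or dwell-time idealization; the half-amplitude rule
  misses events shorter than ~2 samples and biases P_o at low SNR.
* The SANS layer starts from 1-D curves; detector reduction, smearing and
  contrast modelling are out of scope.
* CD band shapes are not fitted; amplitudes are point differences.
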