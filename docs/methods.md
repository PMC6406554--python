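# Methods

This note documents the models, estimators and numerical choices behind
`llpskit`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where several defensible conventions exist.

## FRAP quantification

A FRAP experiment records three regions of interest over time: the bleached
droplet `I_bleached(t)`, an unbleached reference droplet `R(t)` and a
cell-free background. The chain is:

1. **Background subtraction** from both the bleached and reference series.
   Ratio corrections are only valid on offset-free signals, so this happens
   before anything else.
2. **Photofading correction.** Imaging itself bleaches the sample; the
   reference droplet measures that loss. The corrected signal is
   `C_f(t)·I_bleached(t)` with `C_f(t) = R_i / R(t)` and `R_i` the mean
   reference intensity over the pre-bleach frames (averaging suppresses
   single-frame noise; using the mean rather than the first frame changes
   the corrected series only by a constant gain, which the normalization
   below removes).
3. **Normalization.** The post-bleach window is shifted so its minimum is 0
   and scaled so its maximum is 1. When the window minimum is not the
   immediate post-bleach frame but sits within the noise level of it, the
   zero is pinned to the immediate post-bleach point (`noise_tol`
   parameter, default 0).
4. **Recovery fit.** Single-exponential `y = A(1 − e^(−t/τ))` with
   `τ½ = τ ln 2`, or the two-exponential sum
   `A(1 − e^(−t/τ_A)) + B(1 − e^(−t/τ_B))` whose half-time is found
   *graphically*: a bracketed root of `fit(t) = plateau/2` (Brent's method,
   xtol 1e-12). Components are ordered `τ_A ≤ τ_B` to remove
   label-switching; time constants within a factor of 1.5 trigger an
   identifiability warning. With `model="both"`, the model with the lower
   residual RMS is used and the choice is recorded.
5. **Effective bleach radius.** Diffusion during the bleach makes the true
   bleached spot wider than the user-drawn ROI of radius `r_n`. The
   immediate post-bleach profile is fit with the exponential of a Gaussian
   laser profile, `f(x) = exp(−K e^(−2(x−b)²/r_e²))`; `r_e` is defined as
   this fit parameter (the 1/e² Gaussian half-width of the bleach depth).
   Initial guesses come from the data: `b` at the profile minimum,
   `K = −ln(min)`, `r_e` from the width where the log-depth falls to `e⁻²`
   of its central value. A profile whose minimum is ≥ 98% of the plateau is
   rejected as "no detectable bleach".
6. **Derived quantities.** `D_app = (r_e² + r_n²)/(8 τ½)` (μm²/s) and
   `M_f = (I_∞ − I_0)/(I_i − I_0)` on the *corrected, unnormalized*
   intensities. `I_∞` is the fitted plateau mapped back through the
   normalization affine transform rather than the last frame, which is
   robust to truncated recordings; `I_0` is the normalization zero point and
   `I_i` the pre-bleach mean. Mobile fractions outside [0, 1.05] are
   flagged, never clamped. When no profile is available, `r_e := r_n` with a
   recorded warning.

All fits use `scipy.optimize.curve_fit` (trust-region reflective with
bounds) at tolerance 1e-12 with up to three documented starting points
(`llpskit._fitting`). Units are seconds and micrometres throughout.

Out of scope by design: reaction-dominant and full spatial (PDE) FRAP
models — the estimator here is the τ½/effective-radius one — and ROI
drawing or droplet tracking on raw movies.

## Fusion relaxation

Two trapped droplets brought into contact coalesce; the force on the moving
trap relaxes as `F(t) = a e^(−t/τ) + b t + c`, where the linear term absorbs
the constant trap velocity. τ scales linearly with droplet size, so each
event reports `τ / ((r₁+r₂)/2)` (s/μm) and conditions are summarized by the
mean and SEM over ≥ 2 events. Numerical choices:

- Instrument-rate streams (tens of kHz) are block-averaged to ≤ 10 kHz
  before fitting; the fit is sampling-rate invariant (property-tested to
  1e-6) and decimation suppresses white noise.
- The force is normalized by its absolute maximum internally; `a`, `b`, `c`
  are rescaled back, τ is unaffected (affine-invariance is property-tested).
- *Incomplete (arrested) fusion* is operationalized as fitted
  `τ ≥ 0.5 × duration` (or non-convergence). Such events are counted but
  excluded from averages — they have no defined relaxation time. Traces
  shorter than 3 fitted τ are flagged as poorly constrained.
- A trace that is purely linear in time has no relaxation component and is
  rejected rather than fit with a degenerate `a ≈ 0`.
- The event start is taken from the trace as provided; contact detection
  from raw instrument streams is out of scope, as are trap calibration and
  heating corrections.
- An aspect-ratio relaxation fit (`1 + (AR₀−1)e^(−t/τ)`) is provided as the
  image-based cross-check of the force-derived τ, for consistency tests on
  synthetic data.

## Partition analysis

Per image: global Otsu threshold → hole filling → connected components →
area filter (μm²) → per-droplet mean intensity. "Mean intensity of the
entire droplet" includes every pixel inside the mask, rim included (literal
convention). The background is estimated once per image — the complement of
the 2-px-dilated droplet union — and the per-droplet partition coefficient
is droplet mean / background mean, so any multiplicative gain cancels
exactly. Saturation (≥ 1% of pixels at the bit-depth maximum) is flagged.

Condition comparisons use Welch's unequal-variance t-test by default
(conservative for unequal-n intensity ratios; Mann–Whitney available), two
sided, with significance stars binned `*` (0.01, 0.1], `**` (0.001, 0.01],
`***` (0.0001, 0.001], `****` < 0.0001. The `*` bin spanning down from 0.1
is unusually permissive but is the figure-caption convention this field
uses; the bins are overridable. No multiple-testing correction by default
(raw-star convention); Holm correction by flag. Fully tied identical groups
return p = 1 rather than crashing the rank test.

## Phase diagrams

A sample is *separated* iff its A₃₅₀ turbidity is at or above a threshold or
droplets were seen by microscopy; when both readouts exist and disagree,
microscopy wins and a conflict is recorded. The threshold is a required
instrument-dependent setting (default 0.05 above blank, recorded in
output). Per crowder level, `c_sat` is the geometric midpoint
`√(c_mixed_high · c_separated_low)` — concentration titrations are
log-spaced, making the geometric mean the natural interpolant (arithmetic
available by flag). Levels with only one label are censored
("< lowest tested" / "> highest tested"); a mixed point above a separated
one yields a warning and the conservative `c_sat = lowest separated`.
Incubation time is metadata only; no kinetics are modeled, and
temperature-dependent (UCST) boundaries are out of scope.

## Depletion-interaction model

The ternary protein(p)–crowder(c)–solvent(s) mixing free energy per lattice
site (kT) is Flory–Huggins with a depletion augmentation:

    f = (φp/Np) ln φp + (φc/Nc) ln φc + φs ln φs
        + χps φp φs + χcs φc φs + χpc φp φc
        − χ_dep φp φc (φp + φc),        φs = 1 − φp − φc.

The last term is the package's effective encoding of depletion attraction:
overlapping depletion layers free volume to the crowder, producing a net
protein–protein attraction that grows with crowder volume fraction. It is
symmetric under protein↔crowder exchange, vanishes as φc → 0, and
contributes `−2 χ_dep φc` to the protein curvature. By default
`χ_dep = χpc · [(1 + Rc/Rp)³ − 1]`, the contact parameter scaled by the
Asakura–Oosawa overlap-volume factor (equal radii → factor 7), so an
interaction-free crowder (χpc = 0) has no depletion effect. A plain
Flory–Huggins ternary cannot express this physics at fixed crowder
composition: its curvature `1/(Np φp) + 1/φs − 2χps` is independent of χpc
and *rises* with φc, the opposite of what crowding experiments show. The
free-energy form is isolated behind `free_energy_density` so an alternative
(e.g. an explicit virial AO term) can be swapped in.

Derived machinery, all in volume fractions (conversions to μM / mg·mL⁻¹
require partial specific volumes and are reporting-only):

- **Stability.** `∂μ_p/∂φ_p = ∂²f/∂φ_p² = 1/(Np φp) + 1/φs − 2χps −
  2χ_dep φc` (analytic; verified against a Richardson-extrapolated central
  difference of `f` to 1e-6). Positive ⇒ stable homogeneous solution,
  negative ⇒ spinodal decomposition. The derivative decreases monotonically
  with φc wherever `2 χ_dep φs² > 1`; the residual `1/φs` solvent-entropy
  term works the other way and dominates only for weak coupling.
- **Spinodal.** The curvature is convex in φp, so it has 0 or 2 roots;
  found by a 400-point bracketing scan plus Brent refinement (xtol 1e-14).
- **Binodal.** Pseudo-binary common tangent at fixed φc (the crowder does
  not repartition between phases — consistent with holding the crowder
  composition fixed in the stability derivative; full ternary tie-lines are
  a non-goal): solve equal exchange chemical potential and equal
  grand-potential density `ω = f − φp μ` by bounded least squares started
  from the spinodal endpoints (three documented starts, tolerances 1e-15,
  accepted only if residuals ≤ 1e-8). The binodal strictly brackets the
  spinodal at every converged level.
- **Crowding sweep.** Binodal per φc; reports `c_sat = φ_dilute`, the dense
  fraction, the predicted partition `φ_dense/φ_dilute`, and strict
  monotonicity diagnostics. With depletion coupling on, `c_sat` decreases
  and the partition increases with φc — the thermodynamic signature of
  crowding-promoted condensation and maturation. Individual level failures
  are recorded per-row, not raised.
- **Inert-crowder caveat.** With χpc = χcs = 0 the depletion term vanishes,
  but `c_sat` at fixed φc is *not* exactly constant for any free energy
  with three-component mixing entropy: an athermal crowder still displaces
  solvent volume (the `1/φs` term), shifting the pseudo-binary boundary by
  a few percent per percent of crowder volume fraction. The effect is a
  fixed-composition artifact that vanishes as φc → 0; tests bound it at 5%
  over φc ≤ 0.01 rather than asserting exact constancy.

## Synthetic data: what it does and does not emulate

Each generator is the exact inverse of its analysis stage, so zero-noise
round trips recover ground truth to solver precision — that is the design
criterion, and what passing tests demonstrate. Emulated: single/two
component recovery with an immobile floor and multiplicative photofading
shared between bleached and reference ROIs (pre-bleach corrected level 1,
default 1 frame/s, ~300 s traces, bleach depth 0.8, background 0.1);
Gaussian-profile bleach footprints; exponential-plus-drift force traces at
kHz rates (instrument rates add nothing to the fit); top-hat droplet discs
with Gaussian or Poisson (shot) noise; turbidity grids from a known
nonincreasing `c_sat` function with consistent microscopy flags.

Not emulated — so passing tests do not speak to: diffusive spread of the
bleach spot over time (no 2-D+time image stacks), reaction-binding
contributions to recovery, droplet shape dynamics during fusion, optical
trap physics, intensity falloff at droplet rims, spatially varying
background, or turbidity kinetics near the boundary. Estimator behavior on
real data with these features must be validated separately.

Noise is Gaussian by default (the analyses use means, so shot-noise detail
is immaterial); dispersion of every estimator grows monotonically with the
generator noise level (rank-correlation tested).

## Problem sizes

Default test and acceptance runs use: 100-seed noise studies for FRAP
(310-frame traces, 2% noise) and fusion (0.05 pN noise), 50-seed Poisson
partition studies on 128×128 px images, 1000 null simulations for the
comparison's type-I error, 19×5 turbidity grids, and 5-level crowding
sweeps. These sizes give stable medians and rates while keeping a full run
in the tens of seconds on one core.
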