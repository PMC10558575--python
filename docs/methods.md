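# Methods

## State models

Each photosensitizer is a continuous-time linear system over its
electronic states, with S₁ the only emissive state. The transition graphs:

- `MB_FULL_5`: S₀ ⇄ S₁ → T₁ ⇄ T₁H, T₁/T₁H → Ṙ → S₀, T₁ → S₀ (kT1),
  T₁H → S₀ (kT2). Used where the T₁/T₁H ratio is sensitive to the
  protonation rate (buffer titration at pH 5).
- `MB_LOWPH_4`: protonation so fast that T₁ never accumulates; ISC lands
  effectively in T₁H. `MB_HIGHPH_4`: protonation negligible, T₁H omitted.
- `MB_COMPOUND_4`: a single pooled triplet under fast exchange, decaying at
  the equilibrium-weighted compound rate
  kT = (1−f_H)·kT1 + f_H·kT2. The protonated fraction is the
  Henderson–Hasselbalch equilibrium f_H = 1/(1+10^(pH−pKa)); fast exchange
  justifies the pooled description but does not by itself fix the weighting,
  so the equilibrium form is a modelling choice here. When a `kT` value is
  set explicitly on the parameter set it overrides the compound resolution,
  which is how the pH-series fit frees kT per curve.
- `IR700_4` / `IR700_3`: S₀ ⇄ S₁ → T₁ → S₀ with optional photo-reduction
  T₁ → Ṙ⁻ → S₀.

Photo-reduction from T₁ and T₁H uses a single kRED by default (per-state
overrides exist, since reduction of the protonated triplet may be somewhat
faster, but the baseline keeps them equal).

Rate matrices have columns indexed by the source state and columns summing
to zero, so probability is conserved; irradiance enters only through
k01 = σ_exc·Φ_exc, and k10 = 1/τ_f − kISC is derived from the fixed
fluorescence lifetime (345 ps for MB, 4 ns for IR700) — this coupling is
what makes kISC identifiable with σ_exc fixed.

### Units and environmental links

Internal units: rates µs⁻¹, time µs, concentrations mM (matching the scale
of the fitted constants); I/O at the boundary is SI with unit-suffixed
column names. Bimolecular slopes quoted in M⁻¹s⁻¹ convert as
1 M⁻¹s⁻¹ = 10⁻⁹ mM⁻¹µs⁻¹. Dissolved O₂ at air saturation defaults to
0.27 mM (room-temperature water; configurable on `Environment`). All
environment couplings are affine in concentration; KI applies its kQISC1
slope at pH ≤ pKa(T₁) and kQISC2 above (threshold configurable), mirroring
the per-pH-condition fits. kOH is tied to kH through
kOH = kH·10^(pH−pKa(T₁)).

## Kinetics engine

Populations after pulse onset are reconstructed from the eigen
decomposition p(t) = Σᵢ bᵢvᵢe^{λᵢt}, exact for the linear system; one
eigenvalue is ~0 (steady state), the rest have negative real part.
Complex-pair modes are kept in complex arithmetic and the real part taken
at evaluation; imaginary residues are at rounding level. Near-defective
matrices (eigenvector condition number > 1e12) receive a 1e-12 relative
diagonal jitter with a warning — physical parameter sets are generically
diagonalizable, and exact Jordan handling is out of scope. The pulse
average has a closed form per mode, c·φ(λw) with φ(z) = (e^z−1)/z,
evaluated by a 3-term series below |z| < 1e-7.

The default initial condition is unit population in S₀: at duty cycle 0.01
fluorophores recover fully between pulses, so a single pulse represents the
whole train. A validity check warns when the slowest relaxation time
exceeds 10% of the inter-pulse gap at the longest pulse, where the
dark-state build-up (and hence carry-over risk) is largest.

## TRAST simulation

Uniform excitation: ⟨F(w)⟩_norm = ⟨[S]⟩_w / ⟨[S]⟩_w0 directly. Gaussian
beam: the ROI (radius ≤ 1/e² radius) is split into 64 equal-area annuli
(configurable; doubling the count changes values by < 1e-4), the system is
eigen-solved at the mid-area irradiance of each annulus, and annulus
signals are summed with the fluorescence-saturation weight k01/(k01+k10).
The collection efficiency is taken constant over the camera ROI (2-D
widefield treatment, no axial variation), and detection constants cancel
under normalization. Curves carry the ROI-*mean* irradiance; the peak is
reconstructed internally from the mean over the ROI disk. w₀ defaults to
the smallest grid point (100 ns) — short enough for negligible dark-state
build-up, long past the ns anti-bunching rise, which is ignored. The fiber
preset scales the nominal 25 µm 1/e² focal diameter by the calibration
factor 0.7 (18 µm effective).

## FCS model

G(τ) = (1/N̄)(1+τ/τ_D)⁻¹(1+τ/(κ²τ_D))^(−1/2)(1+T̄/(1−T̄)e^(−τ/τ_T)) + offset,
a 3-D Gaussian detection volume with default axial ratio κ = 5. Saturation
broadening of the volume is absorbed by fitting τ_D individually per curve
rather than modelled explicitly. The mapping from photophysical rates to
(T̄, τ_T) uses the steady-state triplet occupancy and the slowest non-zero
relaxation time of the 3-state system, evaluated at an effective irradiance
of half the peak (configurable) as a stand-in for averaging saturation over
the non-uniform detection volume.

## Global fitting

Residuals are concatenated over curves, inverse-variance weighted when
per-point standard errors exist, unweighted otherwise. Free rates are
optimized in log10 space (enforcing positivity across the ~6-decade range
from radical transitions to ISC) with bounds on the natural scale;
scipy's trust-region-reflective least squares does the minimization, with
seeded multi-start restarts from log-uniform perturbations (default 5;
restarts stop early once a numerically exact fit is found). The kISC upper
bound must stay below 1/τ_f so k10 remains positive. Confidence intervals
are linearized: half-width = 1.96·σ with σ² from the inverse
Gauss–Newton Hessian scaled by the residual variance, transformed from log
space by the local derivative (half-width × ln10 × estimate). Whether the
original analysis used linearized or profile intervals is not stated;
these are linearized and labelled as such. Concentration-linked rates are
not a separate layer: the slope symbols are ordinary fit parameters and
the link is applied inside the rate-matrix builder from each curve's
condition metadata, so "linked" layouts are expressed by freeing the slope
symbol globally.

Per-curve model choice (low- vs high-pH reduced model, full 5-state) is
configuration, never auto-detected; the grouped-global layouts ("kT1
global to the high-pH curves") fall out naturally because kT1 only enters
the high-pH model.

## Preprocessing

Chain: subtract the static background (per-pixel frame or scalar) →
divide each frame by a bleaching factor linearly interpolated in
acquisition order between the ≥2 (typically 10) reference-frame
intensities normalized to the first (the interpolation shape between
references is not specified upstream; piecewise-linear is used, and
per-frame division rather than post-hoc curve rescaling) → sum pixels in a
circular ROI centered on the intensity-weighted beam centroid → divide by
pulse count × pulse duration (camera counts are proportional to total
illumination time N·w, so this yields signal per unit illumination time; a
plain division by N would leave a factor w) → normalize by the
shortest-pulse frame. A warning is raised when inferred total bleaching
exceeds 10%. Irradiance maps scale a non-saturating reference-dye image so
that its integral equals the measured laser power; the beam waist is
calibrated by a log-linear fit of intensity against r².

## Synthetic data

The generator emulates: 30-point log-spaced pulse-width grids (100 ns–1
ms), duty cycle 0.01, Gaussian-beam irradiance profiles with saturation
weighting, multiplicative/additive detection noise, ≤10% exponential
photobleaching drift with 10 interleaved reference frames, static
background offsets, and randomized frame acquisition order. Design presets
carry the published condition grids (pH 2–9; PBS 0–12 mM at pH 5; KI
0–10 mM at pH 4 and 0–400 mM at pH 9; O₂ fractions 1–0 of air saturation;
ascorbate 0–2 mM) with the fitted solution parameter sets as ground truth.
The irradiance grids of the irradiance-series figures are not enumerated
upstream; 5-point log grids spanning the quoted values (100–1600 W/cm²
bracketing 431 for MB; 0.5–4.5 kW/cm² for IR700) are used and marked
approximate. KI quenching slopes for the triplet decay (kQT1 = 0.05,
kQT2 = 0.005 mM⁻¹µs⁻¹) are plausible generator values chosen only to
respect kQT1 ≫ kQT2; they are not fitted quantities. Default noise is 1%
multiplicative, 0 additive — bracketing, together with the noiseless
regime, the residual scale visible in the fitted experimental curves.

What the generator does **not** emulate: camera shot-noise statistics,
detector gain/offset maps, flat-field structure, fiber modal speckle, or
photobleaching inside the forward model (bleaching is injected only as a
stack-level corruption). Passing round trips therefore demonstrate the
correctness and identifiability of the estimation machinery under the
stated designs — not robustness to every instrumental artifact of real
recordings.

Two ascorbate slopes for IR700 photo-reduction circulate (0.11 and
0.004 mM⁻¹µs⁻¹, from the tabulated versus in-text values); both are
exposed as named presets (`IR700_TABLE1`, `IR700_TEXT`), with the
tabulated value used as round-trip truth. No reconciliation is attempted.

## Problem sizes and numerical checks

Round trips use the full 30-point grids with 5 irradiances (or 5
titration points) per series and 64 annuli, matching the study's scale;
the Monte-Carlo coverage check (50 seeded noisy repeats) runs a reduced
15-point uniform-beam variant, a deliberate scaled-down setting that keeps
the statistical claim (truth within 3 reported CIs in ≥90% of repeats)
while the per-repeat fit stays cheap. Eigen solutions are validated
against stiff (Radau) ODE integration at rtol 1e-10, and the closed-form
pulse average against adaptive quadrature with breakpoints resolving the
sub-µs singlet boundary layer.

## Known limitations

- No photon-by-photon Monte Carlo, no TCSPC lifetime fitting (lifetimes
  are fixed constants), no singlet-oxygen or iodine-radical chemistry, no
  3-D confocal excitation volume for TRAST, and no pixel-wise TRAST maps
  (ROI-level only).
- The exact upstream expressions for the non-uniform-irradiance and
  saturation corrections (TRAST and FCS) live in supplementary material
  not reproduced here; the annulus integration and effective-irradiance
  approximation are this package's documented choices, validated by
  self-convergence and internal consistency rather than against those
  expressions.
- Linearized CIs underestimate uncertainty for strongly nonlinear or
  near-degenerate layouts; singular information matrices mark CIs
  unavailable rather than guessing.
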