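# trastkit

Transient-state (TRAST) photophysics of photodynamic-therapy
photosensitizers: state models, kinetics, curve simulation, global fitting,
and image-stack preprocessing.

## The problem

Photodynamic therapy (PDT) works through long-lived photo-induced states of
a photosensitizer — the triplet T₁ and photo-reduced radical states — which
generate cytotoxic species. These "PDT precursor" populations depend
strongly on local oxygenation, pH and redox conditions, so monitoring them
*in situ* provides feedback for steering a treatment. TRAST monitoring
infers their kinetics without time-resolved detection: the time-averaged
fluorescence ⟨F⟩ from a rectangular excitation pulse train is recorded as a
function of the pulse duration w; dark-state build-up on the µs–ms scale
shows up as a decay of the normalized curve ⟨F(w)⟩_norm.

`trastkit` implements this analysis for two photosensitizers:

- **Methylene blue (MB)** — a 5-state system S₀, S₁, T₁, T₁H, Ṙ with
  pH/buffer-dependent triplet protonation exchange (pKa(T₁) ≈ 7.2), which
  reduces to 4-state systems at low or high pH.
- **IRdye700DX (IR700)** — a 4-state system S₀, S₁, T₁, Ṙ⁻ (3-state when
  photo-reduction is negligible), used in photoimmunotherapy.

## The model

A fluorophore is a linear rate system dp/dt = M·p over its electronic
states. Excitation drives S₀→S₁ at k01 = σ_exc·Φ_exc with photon flux
Φ = I·λ/(hc); S₁ decays at k10 = 1/τ_f − kISC; intersystem crossing (kISC)
feeds the triplet, which decays (kT), protonates/deprotonates (kH, kOH), or
is photo-reduced (kRED); the radical re-oxidizes to S₀ (kOX). Diagonalizing
M gives populations p(t) = Σᵢ bᵢ vᵢ e^{λᵢt}, and the TRAST observable is the
pulse-averaged singlet probability in closed form per mode:

    ⟨F(w)⟩_norm = [ (1/w)∫₀ʷ [S](t) dt ] / [ same at w₀ ],   [S] = p_S0 + p_S1

with w₀ a sub-µs reference pulse. For a Gaussian beam the signal is a radial
ROI integral weighted by the local saturation factor k01/(k01+k10); the
detection constants cancel under normalization. Under fast protonation
exchange the MB triplet decays at the compound rate
kT = (1−f_H)·kT1 + f_H·kT2 with f_H = 1/(1+10^(pH−pKa)), and environmental
couplings are affine: kH = kH(0) + kH_PBS·[PBS], kT = kT(0) + k_q,O2·[O₂],
kISC = kISC(0) + kQISC·[KI], kRED = kRED(0) + kRED_AA·[AA⁻].

Multi-condition datasets (irradiance series, deoxygenation, pH series,
buffer/KI/ascorbate titrations) are fitted by global nonlinear least
squares with shared, per-curve and concentration-linked parameters, in log
space with seeded multi-starts, reporting linearized 95% confidence
intervals.

## Worked example

```python
from trastkit import (Environment, ExcitationProtocol, BeamProfile,
                      PARAMETER_PRESETS, simulate_trast_curve)
from trastkit.recovery import ir700_roundtrip

# a methylene-blue TRAST curve at low pH, air saturation, 431 W/cm^2
env = Environment(pH=3.5, buffer_mM=12.0)
protocol = ExcitationProtocol.default(431.0)   # 30 w values, 100 ns - 1 ms
curve = simulate_trast_curve("MB_LOWPH_4", PARAMETER_PRESETS["MB_AIR"],
                             env, protocol, BeamProfile(kind="gaussian"))
for i in (0, 10, 20, 29):
    print(f"w = {curve.w_s[i]:.3g} s   <F>_norm = {curve.value[i]:.4f}")

# simulate-and-refit round trip for the IR700 irradiance series
rt = ir700_roundtrip(seed=1)
print(rt.result.report_table())
```

prints

```
w = 1e-07 s   <F>_norm = 1.0000
w = 2.4e-06 s   <F>_norm = 0.9149
w = 5.74e-05 s   <F>_norm = 0.8138
w = 0.001 s   <F>_norm = 0.7894
symbol              estimate        95% CI  unit
kISC                    65.1         1e-11  us^-1
kT                     0.542      9.02e-14  us^-1
```

The MB curve drops ~8% within a few µs (triplet build-up saturating) and
drifts further in the ms range (radical formation). The round trip
simulates noiseless curves at five irradiances from the published ground
truth, perturbs the starting values ×3, and the global fit recovers
kISC = 65.1 µs⁻¹ and kT = 0.542 µs⁻¹ — the generating values — with
essentially zero residual.

The numbered scripts under `analysis/` walk through the full study:
design simulation, the MB global fit, the pH/buffer protonation analysis,
adjuvant (KI, O₂, ascorbate) titrations, and image-stack preprocessing.
Each writes its tables under `results/`. A `trast` command-line tool
exposes `synthesize`, `simulate`, `preprocess`, `fit`-style `recover`, and
`stack` subcommands.

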