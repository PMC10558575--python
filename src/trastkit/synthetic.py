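"""Synthetic TRAST/FCS datasets and camera image stacks.

Reproduces the statistical structure of the study's experimental designs —
irradiance series at low/high pH, deoxygenation, a pH series, buffer and
KI titrations for methylene blue; irradiance, O2 and ascorbate series for
IR700 — so the whole pipeline is testable without the deposited raw data.

Defaults are the study conditions: 30 log-spaced pulse widths from 100 ns
to 1 ms, duty cycle 0.01, Gaussian widefield beam, and the fitted solution
parameter sets as ground truth. Noise magnitudes are configurable (the
experiments report none); the default is 1% multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import kinetics
from .preprocessing import ImageStack
from .state_models import (Environment, RateParameters, PARAMETER_PRESETS,
                           build_rate_matrix, excitation_rate, get_model)
from .trast import (BeamProfile, ExcitationProtocol, TrastCurve,
                    simulate_trast_curve)


@dataclass(frozen=True)
class Condition:
    """One curve's recording condition: solution environment, mean
    irradiance, and the state model the study fits it with."""
    env: Environment
    irradiance_W_cm2: float
    model_id: str


@dataclass(frozen=True)
class NoiseModel:
    mult_sigma: float = 0.01       # relative, multiplicative Gaussian
    add_sigma: float = 0.0         # absolute, post-normalization
    bleach_amplitude: float = 0.0  # fractional intensity loss over a stack

    def __post_init__(self):
        if self.mult_sigma < 0 or self.add_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not (0.0 <= self.bleach_amplitude <= 0.1):
            raise ValueError("bleaching amplitude must be in [0, 0.1]")


NOISELESS = NoiseModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ExperimentDesign:
    design_id: str
    conditions: tuple[Condition, ...]
    truth: RateParameters
    beam: BeamProfile = BeamProfile(kind="gaussian", waist_um=20.0,
                                    roi_radius_um=15.0)
    n_w: int = 30
    w_min_s: float = 100e-9
    w_max_s: float = 1e-3
    wavelength_nm: float = 638.0
    #: symbols the study fit for this design, with their layout kind
    fit_layout: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("design needs at least one condition")

    def protocol(self, irradiance_W_cm2: float) -> ExcitationProtocol:
        return ExcitationProtocol.default(
            irradiance_W_cm2, n_w=self.n_w, w_min_s=self.w_min_s,
            w_max_s=self.w_max_s, wavelength_nm=self.wavelength_nm)


# ---------------------------------------------------------------------------
# design presets
# ---------------------------------------------------------------------------

#: approximate log-spaced irradiance grids spanning the quoted values
MB_IRR_GRID = tuple(np.geomspace(100.0, 1600.0, 5))        # brackets 431 W/cm²
IR700_IRR_GRID = tuple(np.geomspace(500.0, 4500.0, 5))     # up to 4.5 kW/cm²

_ENV_LOWPH = Environment(pH=3.5, buffer_mM=12.0)
_ENV_HIGHPH = Environment(pH=9.3, buffer_mM=12.0)
_ENV_IR700 = Environment(pH=7.2, buffer_mM=12.0)


def _irr_series(env, model_id, grid):
    return tuple(Condition(env, i, model_id) for i in grid)


def _designs() -> dict[str, ExperimentDesign]:
    d = {}
    mb_air = PARAMETER_PRESETS["MB_AIR"]
    d["MB_IRRADIANCE_LOWPH"] = ExperimentDesign(
        "MB_IRRADIANCE_LOWPH",
        _irr_series(_ENV_LOWPH, "MB_LOWPH_4", MB_IRR_GRID), mb_air,
        fit_layout={"kISC": "global", "kT2": "global", "kRED": "global",
                    "kOX": "global"})
    d["MB_IRRADIANCE_HIGHPH"] = ExperimentDesign(
        "MB_IRRADIANCE_HIGHPH",
        _irr_series(_ENV_HIGHPH, "MB_HIGHPH_4", MB_IRR_GRID), mb_air,
        fit_layout={"kISC": "global", "kT1": "global", "kRED": "global",
                    "kOX": "global"})
    d["MB_DEOX"] = ExperimentDesign(
        "MB_DEOX",
        _irr_series(replace(_ENV_LOWPH, O2_fraction=0.0), "MB_LOWPH_4",
                    MB_IRR_GRID)
        + _irr_series(replace(_ENV_HIGHPH, O2_fraction=0.0), "MB_HIGHPH_4",
                      MB_IRR_GRID),
        PARAMETER_PRESETS["MB_DEOX"],
        fit_layout={"kT1": "global", "kT2": "global", "kRED": "global",
                    "kOX": "global"})
    d["MB_PH_SERIES"] = ExperimentDesign(
        "MB_PH_SERIES",
        tuple(Condition(Environment(pH=p, buffer_mM=12.0), 431.0,
                        "MB_COMPOUND_4")
              for p in (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)),
        mb_air, fit_layout={"kT": "per_curve"})
    d["MB_BUFFER_TITRATION"] = ExperimentDesign(
        "MB_BUFFER_TITRATION",
        tuple(Condition(Environment(pH=5.0, buffer_mM=b), 431.0, "MB_FULL_5")
              for b in (0.0, 3.0, 6.0, 9.0, 12.0)),
        mb_air, fit_layout={"kH0": "global", "kH_PBS": "global"})
    d["MB_KI_TITRATION"] = ExperimentDesign(
        "MB_KI_TITRATION",
        tuple(Condition(Environment(pH=4.0, buffer_mM=12.0, KI_mM=c), 431.0,
                        "MB_LOWPH_4") for c in (0.0, 1.0, 2.5, 5.0, 10.0))
        + tuple(Condition(Environment(pH=9.0, buffer_mM=12.0, KI_mM=c), 431.0,
                          "MB_HIGHPH_4")
                for c in (0.0, 50.0, 100.0, 200.0, 400.0)),
        PARAMETER_PRESETS["MB_AIR_KI"],
        fit_layout={"kQISC1": "global", "kQISC2": "global",
                    "kT1": "per_curve", "kT2": "per_curve"})
    d["IR700_IRRADIANCE"] = ExperimentDesign(
        "IR700_IRRADIANCE",
        _irr_series(_ENV_IR700, "IR700_3", IR700_IRR_GRID),
        PARAMETER_PRESETS["IR700_TABLE1"],
        fit_layout={"kISC": "global", "kT": "global"})
    d["IR700_O2_SERIES"] = ExperimentDesign(
        "IR700_O2_SERIES",
        tuple(Condition(replace(_ENV_IR700, O2_fraction=f), 4500.0, "IR700_3")
              for f in (1.0, 0.5, 0.25, 0.1, 0.0)),
        PARAMETER_PRESETS["IR700_O2_LINKED"],
        fit_layout={"kT": "per_curve"})
    d["IR700_AA_TITRATION"] = ExperimentDesign(
        "IR700_AA_TITRATION",
        tuple(Condition(replace(_ENV_IR700, ascorbate_mM=a), 4500.0, "IR700_4")
              for a in (0.0, 0.25, 0.5, 1.0, 2.0)),
        PARAMETER_PRESETS["IR700_TABLE1"],
        fit_layout={"kOX": "global", "kRED_AA": "global", "kT": "per_curve"})
    # fiber-coupled variants: same photophysics, 18 µm 1/e² diameter focus
    d["FIBER_MB"] = replace(
        d["MB_IRRADIANCE_LOWPH"], design_id="FIBER_MB", beam=BeamProfile.fiber())
    d["FIBER_IR700"] = replace(
        d["IR700_IRRADIANCE"], design_id="FIBER_IR700", beam=BeamProfile.fiber())
    return d


DESIGNS = _designs()


def make_design(design_id: str, **overrides) -> ExperimentDesign:
    """Return a design preset, optionally with named fields replaced."""
    if design_id not in DESIGNS:
        raise KeyError(f"unknown design id {design_id!r}; "
                       f"known: {sorted(DESIGNS)}")
    design = DESIGNS[design_id]
    return replace(design, **overrides) if overrides else design


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(design: ExperimentDesign,
                     noise: NoiseModel = NOISELESS,
                     seed: int = 0) -> list[TrastCurve]:
    """One TRAST curve per design condition; reproducible for a fixed seed,
    exactly the forward model when noise is off."""
    rng = np.random.default_rng(seed)
    curves = []
    for cond in design.conditions:
        curve = simulate_trast_curve(
            cond.model_id, design.truth, cond.env,
            design.protocol(cond.irradiance_W_cm2), design.beam,
            check_recovery=False)
        value = curve.value
        if noise.mult_sigma > 0:
            value = value * (1.0 + noise.mult_sigma
                             * rng.standard_normal(value.shape))
        if noise.add_sigma > 0:
            value = value + noise.add_sigma * rng.standard_normal(value.shape)
        se = None
        if noise.mult_sigma > 0 or noise.add_sigma > 0:
            se = np.sqrt((noise.mult_sigma * curve.value) ** 2
                         + noise.add_sigma ** 2)
        curve.meta["design_id"] = design.design_id
        curves.append(TrastCurve(curve.w_s, value, se, curve.meta))
    return curves


# ---------------------------------------------------------------------------
# image-stack simulation (inverse of the preprocessing chain)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackGeometry:
    shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 0.5
    waist_um: float = 10.0
    peak_irradiance_W_cm2: float = 800.0
    roi_radius_um: float = 8.0
    background_offset: float = 5.0
    n_reference: int = 10


def gaussian_reference_image(geom: StackGeometry) -> np.ndarray:
    """Beam profile sampled on the pixel grid (relative units)."""
    h, w = geom.shape
    yy, xx = np.indices((h, w))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * geom.pixel_size_um ** 2
    return np.exp(-2.0 * r2 / geom.waist_um ** 2)


def simulate_image_stack(condition: Condition, truth: RateParameters,
                         noise: NoiseModel = NOISELESS, seed: int = 0,
                         geom: StackGeometry = StackGeometry(),
                         n_w: int = 30, w_min_s: float = 100e-9,
                         w_max_s: float = 1e-3, t_ill_s: float = 0.1,
                         duty_cycle: float = 0.01,
                         wavelength_nm: float = 638.0,
                         ) -> tuple[ImageStack, TrastCurve]:
    """Render camera frames whose ROI sums reproduce the model curve after
    preprocessing; returns the stack together with the generating curve
    (computed on the same pixel grid and ROI).

    Frames carry counts proportional to pulse count × pulse duration ×
    saturation-weighted mean singlet fraction, per pixel; 10 reference
    frames at the shortest pulse width are interleaved; optional
    exponential bleaching drift and a static background offset are
    injected on top.
    """
    rng = np.random.default_rng(seed)
    model = get_model(condition.model_id)
    profile = gaussian_reference_image(geom)
    irr_px = geom.peak_irradiance_W_cm2 * profile           # (h, w)
    w_grid = np.geomspace(w_min_s, w_max_s, n_w)
    w_us = np.append(w_grid, w_grid[0]) * 1e6               # + reference w0

    flat_irr = irr_px.ravel()
    mats = np.stack([build_rate_matrix(model, truth, condition.env,
                                       float(i), wavelength_nm)
                     for i in flat_irr])
    init = np.zeros(model.n_states)
    init[model.index("S0")] = 1.0
    lam, amps = kinetics.eigen_solve_batch(mats, init)
    msf = kinetics.mean_singlet_fraction_batch(
        lam, amps, model.singlet_indices, w_us)             # (px, n_w+1)
    k01 = np.array([excitation_rate(float(i), wavelength_nm,
                                    truth.sigma_exc_cm2) * 1e-6
                    for i in flat_irr])
    sat = (k01 / (k01 + truth.k10))[:, None]
    signal = (sat * msf).reshape(*geom.shape, n_w + 1)      # per unit time

    # the generating curve on this pixel grid and ROI
    h, w_ = geom.shape
    yy, xx = np.indices((h, w_))
    cy, cx = (h - 1) / 2.0, (w_ - 1) / 2.0
    r_um = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) * geom.pixel_size_um
    mask = r_um <= geom.roi_radius_um
    roi_signal = signal[mask].sum(axis=0)
    truth_curve = TrastCurve(
        w_grid, roi_signal[:-1] / roi_signal[-1],
        meta={"model_id": condition.model_id,
              "environment": condition.env.to_dict(),
              "irradiance_W_cm2": float(irr_px[mask].mean()),
              "roi_radius_um": geom.roi_radius_um})

    n_pulses = np.maximum(1, np.round(t_ill_s / w_grid)).astype(int)
    frames = signal[:, :, :n_w].transpose(2, 0, 1) \
        * (n_pulses * w_grid)[:, None, None]                # counts ∝ t_ill
    n_ref = geom.n_reference
    n0 = max(1, round(t_ill_s / w_grid[0]))
    ref_frame = signal[:, :, -1] * (n0 * w_grid[0])

    n_tot = n_w + n_ref
    ref_positions = np.round(np.linspace(0, n_tot - 1, n_ref)).astype(int)
    regular_positions = np.setdiff1d(np.arange(n_tot), ref_positions)
    rng.shuffle(regular_positions)                          # randomized w order

    decay = -np.log1p(-noise.bleach_amplitude) if noise.bleach_amplitude else 0.0

    def bleach_factor(pos):
        return np.exp(-decay * pos / max(1, n_tot - 1))

    frames = frames * bleach_factor(regular_positions.astype(float)
                                    )[:, None, None]
    refs = np.stack([ref_frame * bleach_factor(float(p))
                     for p in ref_positions])

    if noise.mult_sigma > 0:
        frames = frames * (1.0 + noise.mult_sigma
                           * rng.standard_normal(frames.shape))
        refs = refs * (1.0 + noise.mult_sigma
                       * rng.standard_normal(refs.shape))

    frames = frames + geom.background_offset
    refs = refs + geom.background_offset

    stack = ImageStack(
        frames=frames, frame_w_s=w_grid,
        acquisition_index=regular_positions,
        reference_frames=refs, reference_positions=ref_positions,
        reference_w_s=float(w_grid[0]),
        background=geom.background_offset,
        pixel_size_um=geom.pixel_size_um, t_ill_s=t_ill_s,
        duty_cycle=duty_cycle,
        meta={"model_id": condition.model_id,
              "environment": condition.env.to_dict(),
              "peak_irradiance_W_cm2": geom.peak_irradiance_W_cm2,
              "waist_um": geom.waist_um})
    return stack, truth_curve
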