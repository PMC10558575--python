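"""Parameter-recovery round trips: simulate a design from its ground
truth, fit from perturbed starting values, and compare estimates to the
truth. These drivers reproduce the study's fit layouts (which symbols are
global, per-curve, fixed, or concentration-linked for each design) and
back the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .fitting import FitParameter, FitSpec, FitResult, fit_global
from .state_models import RateParameters, compound_triplet_decay
from .synthetic import (ExperimentDesign, NoiseModel, NOISELESS,
                        make_design, simulate_dataset)
from .trast import simulate_trast_curve


def forwards_for(design: ExperimentDesign, base: RateParameters):
    """One forward model per design condition: parameter updates in, curve
    values out. Symbols not updated stay at the ``base`` values, which is
    how the study fixes rates across fits."""
    fns = []
    for cond in design.conditions:
        protocol = design.protocol(cond.irradiance_W_cm2)

        def f(updates, _c=cond, _p=protocol):
            params = base.updated(**updates)
            return simulate_trast_curve(
                _c.model_id, params, _c.env, _p, design.beam,
                check_recovery=False).value
        fns.append(f)
    return fns


def perturbed(value: float, factor: float, direction: int) -> float:
    return value * factor if direction > 0 else value / factor


def _alternating_starts(truth_values: dict[str, float], factor: float):
    """×f/÷f alternating perturbation of the generating truth."""
    out = {}
    for i, (k, v) in enumerate(truth_values.items()):
        out[k] = perturbed(v, factor, +1 if i % 2 == 0 else -1)
    return out


@dataclass
class RoundTrip:
    result: FitResult
    truth: dict[str, float]

    def relative_errors(self) -> dict[str, float]:
        errs = {}
        for k, t in self.truth.items():
            est = self.result.estimates[k]
            est = float(np.mean(est)) if isinstance(est, np.ndarray) else est
            errs[k] = abs(est - t) / abs(t)
        return errs


def mb_global_roundtrip(seed: int = 0, noise: NoiseModel = NOISELESS,
                        start_factor: float = 3.0, n_restarts: int = 2,
                        **design_overrides) -> RoundTrip:
    """The MB headline fit: low- and high-pH air-saturated irradiance
    series fitted jointly, kISC/kRED/kOX global to all curves, kT2 global
    to the low-pH set, kT1 to the high-pH set."""
    low = make_design("MB_IRRADIANCE_LOWPH", **design_overrides)
    high = make_design("MB_IRRADIANCE_HIGHPH", **design_overrides)
    curves = (simulate_dataset(low, noise, seed)
              + simulate_dataset(high, noise, seed + 1))
    base = low.truth
    forwards = forwards_for(low, base) + forwards_for(high, base)

    truth = {"kISC": base.kISC, "kT1": base.kT1, "kT2": base.kT2,
             "kRED": base.kRED, "kOX": base.kOX}
    starts = _alternating_starts(truth, start_factor)
    spec = FitSpec(params={
        "kISC": FitParameter("global", starts["kISC"], (10.0, 2.5e3)),
        "kT1": FitParameter("global", starts["kT1"], (1e-3, 1e2)),
        "kT2": FitParameter("global", starts["kT2"], (1e-3, 1e2)),
        "kRED": FitParameter("global", starts["kRED"], (1e-6, 1.0)),
        "kOX": FitParameter("global", starts["kOX"], (1e-6, 1.0)),
    }, seed=seed, n_restarts=n_restarts)
    return RoundTrip(fit_global(curves, forwards, spec), truth)


def ir700_roundtrip(seed: int = 0, noise: NoiseModel = NOISELESS,
                    start_factor: float = 3.0, n_restarts: int = 2,
                    **design_overrides) -> RoundTrip:
    """IR700 irradiance series, 3-state model: kISC and kT global."""
    design = make_design("IR700_IRRADIANCE", **design_overrides)
    curves = simulate_dataset(design, noise, seed)
    base = design.truth
    truth = {"kISC": base.kISC, "kT": base.kT}
    starts = _alternating_starts(truth, start_factor)
    spec = FitSpec(params={
        "kISC": FitParameter("global", starts["kISC"], (1.0, 240.0)),
        "kT": FitParameter("global", starts["kT"], (1e-3, 1e2)),
    }, seed=seed, n_restarts=n_restarts)
    return RoundTrip(fit_global(curves, forwards_for(design, base), spec), truth)


def buffer_titration_roundtrip(seed: int = 0, noise: NoiseModel = NOISELESS,
                               start_factor: float = 3.0, n_restarts: int = 2,
                               **design_overrides) -> RoundTrip:
    """PBS titration at pH 5, full 5-state model: only the protonation
    intercept kH(0) and the buffer slope kH_PBS are free; kOH is tied to
    kH through the pKa relation inside the rate-matrix builder."""
    design = make_design("MB_BUFFER_TITRATION", **design_overrides)
    curves = simulate_dataset(design, noise, seed)
    base = design.truth
    truth = {"kH0": base.kH0, "kH_PBS": base.kH_PBS}
    starts = _alternating_starts(truth, start_factor)
    spec = FitSpec(params={
        "kH0": FitParameter("global", starts["kH0"], (1e-4, 1e2)),
        "kH_PBS": FitParameter("global", starts["kH_PBS"], (1e-3, 1e2)),
    }, seed=seed, n_restarts=n_restarts)
    return RoundTrip(fit_global(curves, forwards_for(design, base), spec), truth)


def aa_titration_roundtrip(seed: int = 0, noise: NoiseModel = NOISELESS,
                           start_factor: float = 3.0, n_restarts: int = 2,
                           **design_overrides) -> RoundTrip:
    """IR700 ascorbate titration, 4-state model: kISC fixed, kOX and the
    kRED-vs-[AA] slope global, kT per curve."""
    design = make_design("IR700_AA_TITRATION", **design_overrides)
    curves = simulate_dataset(design, noise, seed)
    base = design.truth
    truth = {"kOX": base.kOX, "kRED_AA": base.kRED_AA, "kT": base.kT}
    spec = FitSpec(params={
        "kOX": FitParameter("global",
                            perturbed(base.kOX, start_factor, +1),
                            (1e-6, 1.0)),
        "kRED_AA": FitParameter("global",
                                perturbed(base.kRED_AA, start_factor, -1),
                                (1e-5, 1e2)),
        "kT": FitParameter("per_curve",
                           perturbed(base.kT, start_factor, +1),
                           (1e-3, 1e2)),
    }, seed=seed, n_restarts=n_restarts)
    return RoundTrip(fit_global(curves, forwards_for(design, base), spec), truth)


def ph_series_recovery(seed: int = 0, noise: NoiseModel = NOISELESS,
                       start_factor: float = 3.0, n_restarts: int = 1,
                       **design_overrides):
    """pH series with one free compound triplet decay rate per curve,
    followed by a fit of the protonation-equilibrium sigmoid to the
    recovered kT(pH); returns (RoundTrip, fitted pKa, kT estimates)."""
    design = make_design("MB_PH_SERIES", **design_overrides)
    curves = simulate_dataset(design, noise, seed)
    base = design.truth
    ph = np.array([c.env.pH for c in design.conditions])
    kt_truth = np.array([compound_triplet_decay(p, base.kT1, base.kT2,
                                                base.pKa_T1) for p in ph])

    # the compound model resolves kT from (kT1, kT2, pH) only while kT is
    # unset; setting kT directly frees it as the per-curve fit parameter
    fns = []
    for cond in design.conditions:
        protocol = design.protocol(cond.irradiance_W_cm2)

        def f(updates, _c=cond, _p=protocol):
            params = base.updated(**updates)
            return simulate_trast_curve(
                _c.model_id, params, _c.env, _p, design.beam,
                check_recovery=False).value
        fns.append(f)

    spec = FitSpec(params={
        "kT": FitParameter("per_curve",
                           [perturbed(k, start_factor, +1) for k in kt_truth],
                           (1e-3, 1e2)),
    }, seed=seed, n_restarts=n_restarts)
    result = fit_global(curves, fns, spec)
    kt_est = np.asarray(result.estimates["kT"])

    def sigmoid(p, kT1, kT2, pKa):
        return np.array([compound_triplet_decay(x, kT1, kT2, pKa) for x in p])

    popt, _ = scipy.optimize.curve_fit(
        sigmoid, ph, kt_est, p0=[kt_est[-1], kt_est[0], 7.0])
    pka_fit = float(popt[2])
    return RoundTrip(result, {"pKa_T1": base.pKa_T1}), pka_fit, kt_est


def o2_series_recovery(seed: int = 0, noise: NoiseModel = NOISELESS,
                       start_factor: float = 3.0, n_restarts: int = 1,
                       **design_overrides):
    """IR700 O2 series: kT per curve, then a linear regression of kT
    against [O2] recovers the oxygen quenching slope (mM⁻¹µs⁻¹)."""
    design = make_design("IR700_O2_SERIES", **design_overrides)
    curves = simulate_dataset(design, noise, seed)
    base = design.truth
    o2 = np.array([c.env.O2_mM for c in design.conditions])
    kt_truth = base.kT + base.kq_O2 * o2

    fns = []
    for cond in design.conditions:
        protocol = design.protocol(cond.irradiance_W_cm2)

        def f(updates, _c=cond, _p=protocol):
            params = base.updated(kq_O2=None, **updates)
            return simulate_trast_curve(
                _c.model_id, params, _c.env, _p, design.beam,
                check_recovery=False).value
        fns.append(f)

    spec = FitSpec(params={
        "kT": FitParameter("per_curve",
                           [perturbed(k, start_factor, +1) for k in kt_truth],
                           (1e-3, 1e2)),
    }, seed=seed, n_restarts=n_restarts)
    result = fit_global(curves, fns, spec)
    kt_est = np.asarray(result.estimates["kT"])
    slope, intercept = np.polyfit(o2, kt_est, 1)
    return RoundTrip(result, {"kq_O2": base.kq_O2}), float(slope), float(intercept)


def ki_titration_recovery(seed: int = 0, noise: NoiseModel = NOISELESS,
                          start_factor: float = 3.0, n_restarts: int = 1,
                          **design_overrides) -> RoundTrip:
    """KI titration at low pH: the heavy-atom ISC slope kQISC1 global,
    triplet decay per curve (KI also quenches kT via charge transfer)."""
    design = make_design("MB_KI_TITRATION", **design_overrides)
    low_conditions = tuple(c for c in design.conditions if c.env.pH <= 7)
    design = make_design("MB_KI_TITRATION", conditions=low_conditions,
                         **design_overrides)
    curves = simulate_dataset(design, noise, seed)
    base = design.truth
    ki = np.array([c.env.KI_mM for c in design.conditions])
    kt2_truth = base.kT2 + base.kQT2 * ki

    fns = []
    for cond in design.conditions:
        protocol = design.protocol(cond.irradiance_W_cm2)

        def f(updates, _c=cond, _p=protocol):
            params = base.updated(kQT2=0.0, **updates)
            return simulate_trast_curve(
                _c.model_id, params, _c.env, _p, design.beam,
                check_recovery=False).value
        fns.append(f)

    truth = {"kQISC1": base.kQISC1}
    spec = FitSpec(params={
        "kQISC1": FitParameter("global",
                               perturbed(base.kQISC1, start_factor, +1),
                               (1e-2, 1e3)),
        "kT2": FitParameter("per_curve",
                            [perturbed(k, start_factor, -1)
                             for k in kt2_truth], (1e-3, 1e2)),
    }, seed=seed, n_restarts=n_restarts)
    return RoundTrip(fit_global(curves, fns, spec), truth)
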