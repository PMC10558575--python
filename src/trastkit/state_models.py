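"""Photophysical state models for methylene blue (MB) and IRdye700DX (IR700).

A photosensitizer is modelled as a small continuous-time linear system over
electronic states: ground singlet S0, excited singlet S1 (the only emissive
state), triplet T1, its protonated form T1H (MB only), and a photo-reduced
radical R. Excitation drives S0→S1 at k01 = σ_exc·Φ_exc; intersystem
crossing feeds the triplet manifold; triplet decay, protonation exchange,
photo-reduction and re-oxidation close the cycle back to S0.

Environmental couplings (pH, buffer, KI, ascorbate, dissolved O2) enter as
affine links on individual rates, so the same parameter set describes a
whole titration series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .units import O2_AIR_SAT_MM, photon_flux


class ConfigurationError(ValueError):
    """A model/parameter combination is incomplete or inconsistent."""


# ---------------------------------------------------------------------------
# states and models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotophysicalState:
    id: str
    emissive: bool = False


@dataclass(frozen=True)
class StateModel:
    """A named state system with its transition graph.

    ``transitions`` are (source, destination, rate symbol) triples; the
    symbols are resolved against :class:`RateParameters` + :class:`Environment`
    when the rate matrix is built.
    """

    model_id: str
    states: tuple[PhotophysicalState, ...]
    transitions: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        ids = [s.id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate state ids in {self.model_id}")
        emissive = [s.id for s in self.states if s.emissive]
        if emissive != ["S1"]:
            raise ConfigurationError("exactly S1 must be emissive")
        for src, dst, _ in self.transitions:
            if src not in ids or dst not in ids:
                raise ConfigurationError(
                    f"transition {src}->{dst} references unknown state")

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state_id: str) -> int:
        return self.state_ids.index(state_id)

    @property
    def singlet_indices(self) -> tuple[int, ...]:
        """Indices of the singlet manifold (S0, S1), whose summed population
        is the TRAST observable [S](t)."""
        return tuple(i for i, s in enumerate(self.states) if s.id in ("S0", "S1"))


def _mk(states, transitions, model_id):
    st = tuple(PhotophysicalState(s, emissive=(s == "S1")) for s in states)
    return StateModel(model_id, st, tuple(transitions))


#: Full MB model: unprotonated and protonated triplets in exchange, plus a
#: photo-reduced radical fed from both (equal kRED by default).
MB_FULL_5 = _mk(
    ["S0", "S1", "T1", "T1H", "R"],
    [("S0", "S1", "k01"), ("S1", "S0", "k10"), ("S1", "T1", "kISC"),
     ("T1", "S0", "kT1"), ("T1", "T1H", "kH"), ("T1H", "T1", "kOH"),
     ("T1H", "S0", "kT2"), ("T1", "R", "kRED_T1"), ("T1H", "R", "kRED_T1H"),
     ("R", "S0", "kOX")],
    "MB_FULL_5",
)

#: Low-pH, high-buffer reduction: protonation is so fast that T1 never
#: accumulates; ISC effectively lands in T1H.
MB_LOWPH_4 = _mk(
    ["S0", "S1", "T1H", "R"],
    [("S0", "S1", "k01"), ("S1", "S0", "k10"), ("S1", "T1H", "kISC"),
     ("T1H", "S0", "kT2"), ("T1H", "R", "kRED_T1H"), ("R", "S0", "kOX")],
    "MB_LOWPH_4",
)

#: High-pH reduction: protonation negligible, T1H omitted.
MB_HIGHPH_4 = _mk(
    ["S0", "S1", "T1", "R"],
    [("S0", "S1", "k01"), ("S1", "S0", "k10"), ("S1", "T1", "kISC"),
     ("T1", "S0", "kT1"), ("T1", "R", "kRED_T1"), ("R", "S0", "kOX")],
    "MB_HIGHPH_4",
)

#: Intermediate-pH model with fast protonation exchange: a single compound
#: triplet whose decay is the equilibrium-weighted mix of kT1 and kT2.
MB_COMPOUND_4 = _mk(
    ["S0", "S1", "T1", "R"],
    [("S0", "S1", "k01"), ("S1", "S0", "k10"), ("S1", "T1", "kISC"),
     ("T1", "S0", "kT"), ("T1", "R", "kRED_T1"), ("R", "S0", "kOX")],
    "MB_COMPOUND_4",
)

IR700_4 = _mk(
    ["S0", "S1", "T1", "R"],
    [("S0", "S1", "k01"), ("S1", "S0", "k10"), ("S1", "T1", "kISC"),
     ("T1", "S0", "kT"), ("T1", "R", "kRED_T1"), ("R", "S0", "kOX")],
    "IR700_4",
)

IR700_3 = _mk(
    ["S0", "S1", "T1"],
    [("S0", "S1", "k01"), ("S1", "S0", "k10"), ("S1", "T1", "kISC"),
     ("T1", "S0", "kT")],
    "IR700_3",
)

MODELS: dict[str, StateModel] = {
    m.model_id: m
    for m in (MB_FULL_5, MB_LOWPH_4, MB_HIGHPH_4, MB_COMPOUND_4, IR700_4, IR700_3)
}


def get_model(model_id: str) -> StateModel:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ConfigurationError(f"unknown model id {model_id!r}") from None


# ---------------------------------------------------------------------------
# parameters and environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParameters:
    """Photophysical rate constants, internal units µs⁻¹ / mM⁻¹µs⁻¹.

    ``sigma_exc_cm2`` (cm²) and ``tau_f_s`` (s) fix the excitation rate and
    the S1 decay, with k10 = 1/τ_f − kISC. Quench coefficients (kQ*) are
    affine slopes against the matching :class:`Environment` concentration;
    ``None`` means "no such coupling in this parameter set".
    """

    sigma_exc_cm2: float
    tau_f_s: float
    kISC: float
    kT: Optional[float] = None
    kT1: Optional[float] = None
    kT2: Optional[float] = None
    kRED: Optional[float] = None
    kOX: Optional[float] = None
    kH0: Optional[float] = None          # protonation rate at zero buffer, µs⁻¹
    kH_PBS: Optional[float] = None       # buffer slope of kH, mM⁻¹µs⁻¹
    pKa_T1: Optional[float] = None
    kq_O2: Optional[float] = None        # O2 slope of kT, mM⁻¹µs⁻¹
    kQISC1: Optional[float] = None       # KI slope of kISC at pH <= threshold
    kQISC2: Optional[float] = None       # KI slope of kISC at pH > threshold
    kQT1: Optional[float] = None         # KI slope of kT1
    kQT2: Optional[float] = None         # KI slope of kT2
    kQRED: Optional[float] = None        # KI slope of kRED
    kRED_AA: Optional[float] = None      # ascorbate slope of kRED, mM⁻¹µs⁻¹
    kRED_T1: Optional[float] = None      # per-state override, defaults to kRED
    kRED_T1H: Optional[float] = None
    ki_pH_threshold: Optional[float] = None  # defaults to pKa_T1

    def __post_init__(self):
        if self.tau_f_s <= 0:
            raise ConfigurationError("tau_f must be positive")
        if self.sigma_exc_cm2 <= 0:
            raise ConfigurationError("sigma_exc must be positive")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("k", "kQ")) and v is not None and v < 0:
                raise ConfigurationError(f"rate {f.name} must be >= 0")

    @property
    def k10(self) -> float:
        """S1→S0 decay rate (µs⁻¹), derived from 1/τ_f = k10 + kISC."""
        k = 1e-6 / self.tau_f_s - self.kISC
        if k <= 0:
            raise ConfigurationError(
                "k10 = 1/tau_f - kISC must be positive "
                f"(tau_f={self.tau_f_s} s, kISC={self.kISC} /us)")
        return k

    def updated(self, **changes) -> "RateParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                d[f.name] = v
        return d

    def to_json(self) -> str:
        d = self.to_dict()
        # boundary keys carry the units the field prints in
        d["tau_f_ps"] = d.pop("tau_f_s") * 1e12
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RateParameters":
        d = json.loads(text)
        if "tau_f_ps" in d:
            d["tau_f_s"] = d.pop("tau_f_ps") * 1e-12
        return cls(**d)


@dataclass(frozen=True)
class Environment:
    """Solution conditions a curve was (or is to be) recorded under."""

    pH: float = 7.2
    buffer_mM: float = 12.0
    KI_mM: float = 0.0
    ascorbate_mM: float = 0.0
    O2_fraction: float = 1.0     # fraction of air saturation
    o2_air_sat_mM: float = O2_AIR_SAT_MM

    def __post_init__(self):
        if not (0.0 <= self.pH <= 14.0):
            raise ConfigurationError("pH must be in [0, 14]")
        for name in ("buffer_mM", "KI_mM", "ascorbate_mM", "O2_fraction"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def O2_mM(self) -> float:
        """Dissolved molecular oxygen concentration (mM)."""
        return self.O2_fraction * self.o2_air_sat_mM

    def to_dict(self) -> dict:
        return {"pH": self.pH, "buffer_mM": self.buffer_mM,
                "KI_mM": self.KI_mM, "ascorbate_mM": self.ascorbate_mM,
                "O2_fraction": self.O2_fraction,
                "o2_air_sat_mM": self.o2_air_sat_mM}


# ---------------------------------------------------------------------------
# elementary rate relations
# ---------------------------------------------------------------------------

def excitation_rate(irradiance_W_cm2: float, wavelength_nm: float,
                    sigma_exc_cm2: float) -> float:
    """Excitation rate k01 = σ_exc·Φ_exc in s⁻¹."""
    if sigma_exc_cm2 <= 0:
        raise ValueError("sigma_exc must be positive")
    return sigma_exc_cm2 * photon_flux(irradiance_W_cm2, wavelength_nm)


def protonated_fraction(pH: float, pKa: float) -> float:
    """Equilibrium fraction T1H/(T1+T1H) under fast protonation exchange
    (Henderson–Hasselbalch)."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def compound_triplet_decay(pH: float, kT1: float, kT2: float,
                           pKa_T1: float) -> float:
    """Compound triplet decay rate under fast T1 ⇌ T1H exchange.

    The decay of the pooled triplet is the population-weighted mix of the
    unprotonated (kT1) and protonated (kT2) decay rates.
    """
    if kT1 < 0 or kT2 < 0:
        raise ValueError("triplet decay rates must be >= 0")
    fH = protonated_fraction(pH, pKa_T1)
    return (1.0 - fH) * kT1 + fH * kT2


def linked_rate(base: float, slope: float, conc: float) -> float:
    """Affine concentration link rate(c) = rate(0) + slope·c."""
    if base < 0 or slope < 0 or conc < 0:
        raise ValueError("base, slope and concentration must be >= 0")
    return base + slope * conc


def deprotonation_rate(kH: float, pH: float, pKa_T1: float) -> float:
    """Deprotonation rate kOH tied to the protonation rate through the
    acidity constant: kOH = kH·10^(pH − pKa)."""
    if kH < 0:
        raise ValueError("kH must be >= 0")
    return kH * 10.0 ** (pH - pKa_T1)


# ---------------------------------------------------------------------------
# rate matrix assembly
# ---------------------------------------------------------------------------

def _require(params_value, symbol, model_id):
    if params_value is None:
        raise ConfigurationError(f"model {model_id} requires parameter {symbol}")
    return params_value


def effective_rates(model: StateModel, params: RateParameters,
                    env: Environment, irradiance_W_cm2: float,
                    wavelength_nm: float = 638.0) -> dict[str, float]:
    """Resolve every rate symbol of ``model`` to a value in µs⁻¹, applying
    the environment links of the parameter set."""
    p, e = params, env
    mid = model.model_id
    out: dict[str, float] = {}

    ki = e.KI_mM
    thresh = p.ki_pH_threshold if p.ki_pH_threshold is not None else p.pKa_T1
    kQISC = 0.0
    if ki > 0:
        if thresh is None or e.pH <= thresh:
            kQISC = p.kQISC1 or 0.0
        else:
            kQISC = p.kQISC2 or 0.0

    kISC_eff = linked_rate(p.kISC, kQISC, ki)
    kRED_base = p.kRED if p.kRED is not None else 0.0
    kRED_eff = kRED_base + (p.kQRED or 0.0) * ki + (p.kRED_AA or 0.0) * e.ascorbate_mM

    needed = {sym for _, _, sym in model.transitions}
    for sym in needed:
        if sym == "k01":
            out[sym] = excitation_rate(irradiance_W_cm2, wavelength_nm,
                                       p.sigma_exc_cm2) * 1e-6
        elif sym == "k10":
            out[sym] = p.k10
        elif sym == "kISC":
            out[sym] = kISC_eff
        elif sym == "kT1":
            out[sym] = linked_rate(_require(p.kT1, sym, mid), p.kQT1 or 0.0, ki)
        elif sym == "kT2":
            out[sym] = linked_rate(_require(p.kT2, sym, mid), p.kQT2 or 0.0, ki)
        elif sym == "kT":
            if mid == "MB_COMPOUND_4" and p.kT is None:
                # fast-exchange compound decay from the protonation equilibrium
                kT1 = linked_rate(_require(p.kT1, "kT1", mid), p.kQT1 or 0.0, ki)
                kT2 = linked_rate(_require(p.kT2, "kT2", mid), p.kQT2 or 0.0, ki)
                out[sym] = compound_triplet_decay(
                    e.pH, kT1, kT2, _require(p.pKa_T1, "pKa_T1", mid))
            else:
                out[sym] = linked_rate(_require(p.kT, sym, mid),
                                       p.kq_O2 or 0.0, e.O2_mM)
        elif sym == "kRED_T1":
            base = p.kRED_T1 if p.kRED_T1 is not None else kRED_eff
            out[sym] = base
        elif sym == "kRED_T1H":
            base = p.kRED_T1H if p.kRED_T1H is not None else kRED_eff
            out[sym] = base
        elif sym == "kOX":
            out[sym] = _require(p.kOX, sym, mid)
        elif sym == "kH":
            kH0 = _require(p.kH0, "kH0", mid)
            out[sym] = linked_rate(kH0, p.kH_PBS or 0.0, e.buffer_mM)
        elif sym == "kOH":
            kH0 = _require(p.kH0, "kH0", mid)
            kH = linked_rate(kH0, p.kH_PBS or 0.0, e.buffer_mM)
            out[sym] = deprotonation_rate(kH, e.pH,
                                          _require(p.pKa_T1, "pKa_T1", mid))
        else:  # pragma: no cover - guarded by model construction
            raise ConfigurationError(f"unresolved rate symbol {sym}")
    return out


def build_rate_matrix(model: StateModel, params: RateParameters,
                      env: Environment, irradiance_W_cm2: float,
                      wavelength_nm: float = 638.0) -> np.ndarray:
    """Assemble the first-order rate matrix M (µs⁻¹), columns indexed by the
    source state, so that dp/dt = M·p and every column sums to zero."""
    rates = effective_rates(model, params, env, irradiance_W_cm2, wavelength_nm)
    n = model.n_states
    M = np.zeros((n, n))
    for src, dst, sym in model.transitions:
        k = rates[sym]
        i, j = model.index(dst), model.index(src)
        M[i, j] += k
        M[j, j] -= k
    return M


# ---------------------------------------------------------------------------
# parameter presets (fitted solution values; fixed photophysical constants)
# ---------------------------------------------------------------------------

def _mb_base(**kw):
    d = dict(sigma_exc_cm2=1.9e-16, tau_f_s=345e-12, kISC=1150.0,
             pKa_T1=7.2, kH0=0.1, kH_PBS=0.508)
    d.update(kw)
    return RateParameters(**d)


#: MB in air-saturated PBS.
MB_AIR = _mb_base(kT1=0.825, kT2=0.473, kRED=0.00096, kOX=0.00507)

#: MB after nitrogen deoxygenation.
MB_DEOX = _mb_base(kT1=0.171, kT2=0.325, kRED=0.0007, kOX=0.013)

#: MB with KI quench couplings (slopes in mM⁻¹µs⁻¹; kQT1/kQT2 are
#: approximate generator values, the study reports only kQT1 >> kQT2).
MB_AIR_KI = MB_AIR.updated(kQISC1=49.1, kQISC2=3.4, kQRED=1e-5,
                           kQT1=0.05, kQT2=0.005, kRED=0.001)

#: IR700 in air-saturated PBS (headline fitted values).
IR700_TABLE1 = RateParameters(
    sigma_exc_cm2=0.76e-16, tau_f_s=4e-9, kISC=65.1, kT=0.542,
    kRED=0.0, kOX=0.00468, kRED_AA=0.11)

#: IR700 with the alternative, smaller ascorbate slope quoted in the text.
IR700_TEXT = IR700_TABLE1.updated(kRED_AA=0.004)

#: IR700 with kT split into a zero-O2 intercept plus an O2 quench slope;
#: intercept chosen so air saturation reproduces the fitted kT.
IR700_O2_LINKED = IR700_TABLE1.updated(
    kT=0.542 - 1.5 * O2_AIR_SAT_MM, kq_O2=1.5)

PARAMETER_PRESETS: dict[str, RateParameters] = {
    "MB_AIR": MB_AIR,
    "MB_DEOX": MB_DEOX,
    "MB_AIR_KI": MB_AIR_KI,
    "IR700_TABLE1": IR700_TABLE1,
    "IR700_TEXT": IR700_TEXT,
    "IR700_O2_LINKED": IR700_O2_LINKED,
}
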