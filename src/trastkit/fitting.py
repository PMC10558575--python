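"""Global nonlinear least squares over multi-condition curve sets.

Parameters are tagged global (one value shared by all curves), per-curve
(one value per curve), or fixed. Concentration-linked rates are handled by
the rate-matrix builder: the slope symbols (kH_PBS, kq_O2, kQISC1, ...)
are ordinary parameters here, and the link reads the concentration from
each curve's condition metadata.

Free rates are optimized in log10 space (positivity plus the wide dynamic
range between ISC and radical transitions); a seeded multi-start scheme
restarts the trust-region optimizer from log-uniform perturbations and
keeps the best solution. 95% confidence intervals are linearized:
half-width = 1.96·sqrt(diag cov), with the covariance scaled by the
residual variance at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.optimize


@dataclass
class FitParameter:
    """One symbol of the fit layout."""

    kind: str                           # "global" | "per_curve" | "fixed"
    value: float | Sequence[float]      # initial (or fixed) value(s)
    bounds: tuple[float, float] = (1e-8, 1e5)

    def __post_init__(self):
        if self.kind not in ("global", "per_curve", "fixed"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        lo, hi = self.bounds
        if self.kind != "fixed" and (lo <= 0 or hi <= lo):
            raise ValueError("free parameters need bounds 0 < lo < hi")


@dataclass
class FitSpec:
    params: dict[str, FitParameter]
    n_restarts: int = 5
    perturb_factor: float = 3.0
    seed: int = 0
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: Optional[int] = None


@dataclass
class FitResult:
    estimates: dict[str, float | np.ndarray]
    ci95: dict[str, float | np.ndarray | None]
    chi2: float
    residuals: list[np.ndarray]
    cov_log10: Optional[np.ndarray]
    free_labels: list[tuple[str, Optional[int]]]
    converged: bool
    message: str
    n_points: int
    n_free: int
    start_costs: list[float] = field(default_factory=list)

    def estimate(self, name: str, curve: Optional[int] = None) -> float:
        v = self.estimates[name]
        return float(v[curve]) if curve is not None else float(v)

    def to_json(self) -> str:
        def conv(d):
            return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in d.items()}
        return json.dumps({
            "estimates": conv(self.estimates),
            "ci95": conv(self.ci95),
            "chi2": self.chi2,
            "converged": self.converged,
            "message": self.message,
            "n_points": self.n_points,
            "n_free": self.n_free,
        }, indent=2, sort_keys=True)

    def report_table(self, units: dict[str, str] | None = None) -> str:
        """Human-readable estimate ± 95% CI table."""
        units = units or {}
        lines = [f"{'symbol':<14}{'estimate':>14}{'95% CI':>14}  unit"]
        for name, est in self.estimates.items():
            ci = self.ci95.get(name)
            u = units.get(name, "us^-1")
            if isinstance(est, np.ndarray):
                for i, (e, c) in enumerate(zip(np.atleast_1d(est),
                                               np.atleast_1d(ci))):
                    lines.append(f"{name}[{i}]".ljust(14)
                                 + f"{e:>14.6g}{c if c is not None else float('nan'):>14.3g}  {u}")
            else:
                cstr = f"{ci:>14.3g}" if ci is not None else f"{'n/a':>14}"
                lines.append(f"{name:<14}{est:>14.6g}{cstr}  {u}")
        return "\n".join(lines)


def _pack_layout(spec: FitSpec, n_curves: int):
    """Free-parameter vector layout: list of (symbol, curve index or None)."""
    labels: list[tuple[str, Optional[int]]] = []
    for name, p in spec.params.items():
        if p.kind == "global":
            labels.append((name, None))
        elif p.kind == "per_curve":
            vals = np.atleast_1d(np.asarray(p.value, dtype=float))
            if vals.size == 1:
                vals = np.full(n_curves, vals[0])
            if vals.size != n_curves:
                raise ValueError(
                    f"per-curve parameter {name} needs {n_curves} initials")
            labels.extend((name, i) for i in range(n_curves))
    return labels


def _initial_vector(spec: FitSpec, labels) -> np.ndarray:
    x0 = []
    for name, idx in labels:
        p = spec.params[name]
        v = np.atleast_1d(np.asarray(p.value, dtype=float))
        x0.append(v[0] if idx is None or v.size == 1 else v[idx])
    return np.log10(np.asarray(x0))


def _params_for_curve(spec: FitSpec, labels, x: np.ndarray, curve: int) -> dict:
    out = {}
    for name, p in spec.params.items():
        if p.kind == "fixed":
            v = np.atleast_1d(np.asarray(p.value, dtype=float))
            out[name] = float(v[0] if v.size == 1 else v[curve])
    for (name, idx), xv in zip(labels, x):
        if idx is None or idx == curve:
            out[name] = 10.0 ** xv
    return out


def fit_global(curves: Sequence, forwards: Sequence[Callable[[dict], np.ndarray]],
               spec: FitSpec) -> FitResult:
    """Fit shared/per-curve parameters to a set of curves.

    ``forwards[i]`` maps a {symbol: value} dict to the model prediction on
    curve i's abscissa grid. Residuals are inverse-variance weighted when a
    curve carries per-point standard errors, unweighted otherwise.
    """
    if len(curves) != len(forwards):
        raise ValueError("one forward model per curve required")
    n_curves = len(curves)
    labels = _pack_layout(spec, n_curves)
    if not labels:
        raise ValueError("no free parameters in fit spec")

    ys, ses = [], []
    for c in curves:
        y = getattr(c, "value", None)
        if y is None:
            y = getattr(c, "G")
        ys.append(np.asarray(y, dtype=float))
        se = getattr(c, "se", None)
        ses.append(np.ones_like(ys[-1]) if se is None else np.asarray(se))

    def residuals(x):
        parts = []
        for i in range(n_curves):
            pred = forwards[i](_params_for_curve(spec, labels, x, i))
            parts.append((pred - ys[i]) / ses[i])
        return np.concatenate(parts)

    lo = np.array([np.log10(spec.params[n].bounds[0]) for n, _ in labels])
    hi = np.array([np.log10(spec.params[n].bounds[1]) for n, _ in labels])
    x0 = np.clip(_initial_vector(spec, labels), lo, hi)

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(max(0, spec.n_restarts - 1)):
        jitter = rng.uniform(-np.log10(spec.perturb_factor),
                             np.log10(spec.perturb_factor), size=x0.size)
        starts.append(np.clip(x0 + jitter, lo, hi))

    best = None
    start_costs = []
    for s in starts:
        res = scipy.optimize.least_squares(
            residuals, s, bounds=(lo, hi), method="trf",
            xtol=spec.xtol, ftol=spec.ftol, gtol=spec.gtol,
            max_nfev=spec.max_nfev, x_scale="jac")
        start_costs.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-22 * max(1, sum(y.size for y in ys)):
            break  # numerically exact fit; further restarts are moot

    x = best.x
    n_points = sum(y.size for y in ys)
    n_free = len(labels)
    chi2 = float(2.0 * best.cost)

    cov_log10, ci_vals = _linearized_ci(best, n_points, n_free)

    estimates: dict[str, float | np.ndarray] = {}
    ci95: dict[str, float | np.ndarray | None] = {}
    for name, p in spec.params.items():
        if p.kind == "fixed":
            continue
        if p.kind == "global":
            j = labels.index((name, None))
            estimates[name] = 10.0 ** x[j]
            ci95[name] = (None if ci_vals is None
                          else ci_vals[j] * np.log(10) * estimates[name])
        else:
            idxs = [j for j, (n2, i) in enumerate(labels) if n2 == name]
            vals = 10.0 ** x[idxs]
            estimates[name] = vals
            ci95[name] = (None if ci_vals is None
                          else ci_vals[idxs] * np.log(10) * vals)

    per_curve_res = []
    off = 0
    r = best.fun
    for y in ys:
        per_curve_res.append(r[off:off + y.size])
        off += y.size

    return FitResult(
        estimates=estimates, ci95=ci95, chi2=chi2, residuals=per_curve_res,
        cov_log10=cov_log10, free_labels=labels,
        converged=bool(best.status > 0), message=str(best.message),
        n_points=n_points, n_free=n_free, start_costs=start_costs)


def _linearized_ci(res, n_points: int, n_free: int):
    """Covariance (log10 space) and 1.96·σ half-widths from the Jacobian."""
    dof = n_points - n_free
    if dof <= 0:
        return None, None
    J = res.jac
    try:
        JTJ = J.T @ J
        cov = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        return None, None
    if not np.all(np.isfinite(cov)):
        return None, None
    s2 = 2.0 * res.cost / dof
    cov = cov * s2
    diag = np.clip(np.diag(cov), 0.0, None)
    return cov, 1.96 * np.sqrt(diag)


def confidence_intervals(result: FitResult) -> dict[str, float | np.ndarray | None]:
    """Per-symbol 95% half-widths on the natural scale (linearized)."""
    return result.ci95
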