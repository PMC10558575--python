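"""Eigen-solution of the excitation-driven rate equations.

For a rate matrix M (columns summing to zero) the populations after
excitation onset are p(t) = Σ_i b_i v_i e^{λ_i t}, where (λ_i, v_i) are the
eigenpairs of M and b = V⁻¹ p(0). One eigenvalue is zero and carries the
steady state; all others have negative real part. The singlet-manifold
population [S](t) = p_S0(t) + p_S1(t) and its pulse average
(1/w)∫₀ʷ [S] dt — the TRAST observable — follow in closed form per mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg


class DegenerateSystemError(RuntimeError):
    pass


@dataclass
class EigenSolution:
    """Eigen decomposition of one rate system.

    ``amplitudes[s, i]`` is the (complex) coefficient of mode i in the
    population of state s: p_s(t) = Re Σ_i amplitudes[s, i]·e^{eigenvalues[i]·t}.
    """

    eigenvalues: np.ndarray      # (n,), complex, µs⁻¹
    amplitudes: np.ndarray       # (n_states, n), complex
    init: np.ndarray             # (n_states,)
    singlet_indices: tuple[int, ...] = (0, 1)
    perturbed: bool = False      # True if degeneracy jitter was applied

    @property
    def singlet_mode_weights(self) -> np.ndarray:
        """Per-mode coefficients of [S](t) = Σ_i c_i e^{λ_i t}."""
        return self.amplitudes[list(self.singlet_indices), :].sum(axis=0)


def _eig_with_fallback(M: np.ndarray, rng_jitter: float = 1e-12):
    lam, V = np.linalg.eig(M)
    # defective matrices: nearly parallel eigenvectors -> ill-conditioned V
    if np.linalg.cond(V) > 1e12:
        warnings.warn("near-degenerate rate matrix; applying 1e-12 relative "
                      "jitter to restore diagonalizability", RuntimeWarning)
        scale = np.max(np.abs(M))
        jitter = rng_jitter * scale * np.diag(np.arange(1, M.shape[0] + 1))
        lam, V = np.linalg.eig(M + jitter)
        return lam, V, True
    return lam, V, False


def eigen_solve(M: np.ndarray, init: np.ndarray | None = None,
                singlet_indices: tuple[int, ...] = (0, 1)) -> EigenSolution:
    """Diagonalize a rate matrix and project the initial condition.

    ``init`` defaults to all population in the first state (S0), matching a
    fluorophore fully relaxed before pulse onset.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if init is None:
        init = np.zeros(n)
        init[0] = 1.0
    init = np.asarray(init, dtype=float)
    if np.any(init < -1e-12) or abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("init must be a probability vector")

    lam, V, perturbed = _eig_with_fallback(M)
    b = np.linalg.solve(V, init.astype(complex))
    B = V * b[np.newaxis, :]
    return EigenSolution(eigenvalues=lam, amplitudes=B, init=init,
                         singlet_indices=singlet_indices, perturbed=perturbed)


def eigen_solve_batch(Ms: np.ndarray, init: np.ndarray):
    """Vectorized eigen decomposition for a stack of rate matrices.

    Returns (eigenvalues (B, n), amplitudes (B, n_states, n)). Used by the
    beam-profile integration where one system is solved per annulus.
    """
    lam, V = np.linalg.eig(Ms)                       # (B, n), (B, n, n)
    rhs = np.broadcast_to(init.astype(complex),
                          (Ms.shape[0], Ms.shape[1]))[..., None]
    b = np.linalg.solve(V, rhs)                      # (B, n, 1)
    return lam, V * np.swapaxes(b, -1, -2)           # amplitudes (B, state, mode)


def populations_at(sol: EigenSolution, t) -> np.ndarray:
    """State populations at time(s) t ≥ 0 (µs).

    Returns shape (n_states,) for scalar t, else (n_states, len(t)).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    expo = np.exp(np.multiply.outer(sol.eigenvalues, t_arr))  # (n, ...) complex
    p = np.real(np.tensordot(sol.amplitudes, expo, axes=(1, 0)))
    return p


def _phi(z: np.ndarray) -> np.ndarray:
    """(e^z − 1)/z with the removable singularity at z = 0 filled in."""
    z = np.asarray(z, dtype=complex)
    small = np.abs(z) < 1e-7
    zs = np.where(small, 1.0, z)
    out = (np.exp(zs) - 1.0) / zs
    series = 1.0 + z / 2.0 + z * z / 6.0
    return np.where(small, series, out)


def mean_singlet_fraction(sol: EigenSolution, w) -> np.ndarray | float:
    """Pulse-averaged singlet probability ⟨[S]⟩_w = (1/w)∫₀ʷ [S](t) dt.

    Closed form per exponential mode: a mode c·e^{λt} averages to c·φ(λw)
    with φ(z) = (e^z − 1)/z; the zero eigenvalue contributes its constant.
    ``w`` in µs, scalar or array.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr <= 0):
        raise ValueError("pulse duration must be positive")
    c = sol.singlet_mode_weights                     # (n,)
    z = np.multiply.outer(w_arr, sol.eigenvalues)    # (..., n)
    vals = np.real(_phi(z) @ c)
    if np.isscalar(w) or w_arr.ndim == 0:
        return float(vals)
    return vals


def mean_singlet_fraction_batch(lam: np.ndarray, amps: np.ndarray,
                                singlet_indices, w_us: np.ndarray) -> np.ndarray:
    """Batched pulse average: lam (B, n), amps (B, n_states, n), w (m,).

    Returns (B, m).
    """
    c = amps[:, list(singlet_indices), :].sum(axis=1)        # (B, n)
    z = lam[:, None, :] * w_us[None, :, None]                # (B, m, n)
    return np.real(np.einsum("bmn,bn->bm", _phi(z), c))


def steady_state(M: np.ndarray) -> np.ndarray:
    """Normalized null-space vector of M: the long-time population."""
    ns = scipy.linalg.null_space(M, rcond=1e-10)
    if ns.shape[1] != 1:
        raise DegenerateSystemError(
            f"ambiguous steady state (null space dimension {ns.shape[1]})")
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-9):
        raise DegenerateSystemError("steady state has negative components")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def slowest_relaxation_time(M: np.ndarray) -> float:
    """1/|Re λ| of the slowest non-zero mode (µs); used to validate the
    complete-recovery assumption between pulses."""
    lam = np.linalg.eigvals(M)
    nz = lam[np.abs(lam) > 1e-12 * max(1.0, np.max(np.abs(lam)))]
    if nz.size == 0:
        return 0.0
    return float(1.0 / np.min(np.abs(np.real(nz))))
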