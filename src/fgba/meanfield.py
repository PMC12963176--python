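"""Nonspatial mean-field FGBA dynamics.

In the well-mixed (uniform-kernel, many-site) limit the landscape is described
by the four cover fractions (F, G, B, A) on the 3-simplex, evolving as

    dF/dt = (phi_G G + phi_A A) F - beta_F B F - Phi_F(G) F - mu F
    dG/dt = gamma A + mu F - phi_G F G - Phi_G(G) G - beta_G B G
    dB/dt = Phi_G(G) G + Phi_F(G) F + (beta_G G + beta_F F) B - q B
    dA/dt = q B - gamma A - phi_A F A

with the sigmoidal flammabilities Phi_F, Phi_G of the grass fraction.  The
forest-free boundary F = 0 is invariant; eliminating A = 1 - G - B there gives
the two-dimensional grass-fire (GBA) subsystem

    dG/dt = gamma (1 - G - B) - Phi_G(G) G - beta_G B G
    dB/dt = Phi_G(G) G + beta_G G B - q B.

Rates span many orders of magnitude under realistic timescale separation, so
all integration here uses stiff-capable solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ParameterSet
from .trajectory import Trajectory

__all__ = [
    "MeanFieldState",
    "rhs_fgba",
    "rhs_gba",
    "jacobian_reduced",
    "integrate",
    "integrate_gba",
    "settle_to_equilibrium",
    "SettleError",
]


@dataclass(frozen=True)
class MeanFieldState:
    """A point (F, G, B, A) of cover fractions on the 3-simplex."""

    F: float
    G: float
    B: float
    A: float

    def __post_init__(self):
        vec = self.as_array()
        if np.any(vec < -1e-9) or np.any(vec > 1 + 1e-9):
            raise ValueError("cover fractions must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("cover fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.G, self.B, self.A], dtype=float)

    @classmethod
    def from_array(cls, x) -> "MeanFieldState":
        x = np.asarray(x, dtype=float)
        if x.size == 3:  # reduced coordinates, close A
            x = np.append(x, 1.0 - x.sum())
        x = np.clip(x, 0.0, 1.0)
        x = x / x.sum()
        return cls(*x)


def rhs_fgba(state, params: ParameterSet) -> np.ndarray:
    """Time derivatives (dF, dG, dB, dA) of the mean-field system.

    ``state`` may be a :class:`MeanFieldState` or a length-4 array; it is
    evaluated as given (also outside the simplex, for root finding).  The four
    derivatives sum to zero exactly.
    """
    F, G, B, A = _as4(state)
    p = params
    PF = p.Phi_F(G)
    PG = p.Phi_G(G)
    dF = (p.phi_G * G + p.phi_A * A) * F - p.beta_F * B * F - PF * F - p.mu * F
    dG = p.gamma * A + p.mu * F - p.phi_G * F * G - PG * G - p.beta_G * B * G
    dB = PG * G + PF * F + (p.beta_G * G + p.beta_F * F) * B - p.q * B
    dA = p.q * B - p.gamma * A - p.phi_A * F * A
    return np.array([dF, dG, dB, dA])


def rhs_gba(gb, params: ParameterSet) -> np.ndarray:
    """Time derivatives (dG, dB) of the forest-free subsystem (A eliminated)."""
    G, B = float(gb[0]), float(gb[1])
    p = params
    PG = p.Phi_G(G)
    dG = p.gamma * (1.0 - G - B) - PG * G - p.beta_G * B * G
    dB = PG * G + p.beta_G * G * B - p.q * B
    return np.array([dG, dB])


def _as4(state) -> np.ndarray:
    if isinstance(state, MeanFieldState):
        return state.as_array()
    x = np.asarray(state, dtype=float)
    if x.size != 4:
        raise ValueError("state must have four components (F, G, B, A)")
    return x


def _rhs3(x, params: ParameterSet) -> np.ndarray:
    """Reduced vector field in (F, G, B) with A = 1 - F - G - B."""
    F, G, B = x
    return rhs_fgba((F, G, B, 1.0 - F - G - B), params)[:3]


def _phi_prime(x, lo, hi, theta, s):
    z = (x - theta) / s
    e = np.exp(-abs(z))
    sig = e / (1.0 + e) ** 2  # logistic' computed stably (even in z)
    return (hi - lo) / s * sig


def jacobian_reduced(x, params: ParameterSet) -> np.ndarray:
    """Analytic 3x3 Jacobian of the reduced (F, G, B) vector field."""
    F, G, B = x
    p = params
    A = 1.0 - F - G - B
    PF = p.Phi_F(G)
    PG = p.Phi_G(G)
    dPF = _phi_prime(G, p.f0, p.f1, p.theta_F, p.s_F)
    dPG = _phi_prime(G, p.g0, p.g1, p.theta_G, p.s_G)
    J = np.empty((3, 3))
    J[0, 0] = p.phi_G * G + p.phi_A * A - p.phi_A * F - p.beta_F * B - PF - p.mu
    J[0, 1] = (p.phi_G - p.phi_A) * F - dPF * F
    J[0, 2] = -(p.phi_A + p.beta_F) * F
    J[1, 0] = -p.gamma + p.mu - p.phi_G * G
    J[1, 1] = -p.gamma - p.phi_G * F - dPG * G - PG - p.beta_G * B
    J[1, 2] = -p.gamma - p.beta_G * G
    J[2, 0] = PF + p.beta_F * B
    J[2, 1] = dPG * G + PG + dPF * F + p.beta_G * B
    J[2, 2] = p.beta_G * G + p.beta_F * F - p.q
    return J


def integrate(x0, params: ParameterSet, t_end, tol=1e-9, t_eval=None,
              method="LSODA") -> Trajectory:
    """Integrate the mean-field system with a stiff-capable method.

    Three components (F, G, B) are integrated and A closed as 1 - F - G - B,
    so the total cover is conserved by construction.  The solution stays on
    the simplex to within the integration tolerance (forward invariance).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = _as4(x0)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(
        lambda t, y: _rhs3(y, params), (0.0, float(t_end)), x0[:3],
        method=method, t_eval=np.asarray(t_eval, dtype=float),
        jac=lambda t, y: jacobian_reduced(y, params),
        rtol=tol, atol=tol * 1e-2)
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1]}")
    fgb = np.clip(sol.y.T, 0.0, 1.0)
    frac = np.column_stack([fgb, np.clip(1.0 - fgb.sum(axis=1), 0.0, 1.0)])
    frac /= frac.sum(axis=1, keepdims=True)
    return Trajectory(times=sol.t, fractions=frac)


def integrate_gba(gb0, params: ParameterSet, t_end, tol=1e-9, t_eval=None) -> tuple:
    """Integrate the forest-free (G, B) subsystem; returns (times, G, B)."""
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(lambda t, y: rhs_gba(y, params), (0.0, float(t_end)),
                    [float(gb0[0]), float(gb0[1])], method="LSODA",
                    t_eval=np.asarray(t_eval, dtype=float),
                    rtol=tol, atol=tol * 1e-2)
    if not sol.success:
        raise RuntimeError(f"GBA integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


class SettleError(RuntimeError):
    """Raised when no equilibrium is reached; carries the last state seen."""

    def __init__(self, message, last_state):
        super().__init__(message)
        self.last_state = last_state


def settle_to_equilibrium(x0, params: ParameterSet, rhs_tol=1e-8,
                          t_max=1e4) -> MeanFieldState:
    """Integrate to stationarity, then Newton-polish the equilibrium.

    The system is integrated over time horizons that double until the maximum
    derivative magnitude drops below ``rhs_tol`` (1/yr), after which the
    algebraic system rhs = 0 is polished in the reduced (F, G, B) coordinates.
    If the trajectory collapses onto the forest-free boundary the polish is
    done within the GBA subsystem so that F stays exactly zero.
    """
    y = _as4(x0)[:3].copy()
    t = 50.0
    settled = False
    while True:
        sol = solve_ivp(lambda tt, yy: _rhs3(yy, params), (0.0, t), y,
                        method="LSODA",
                        jac=lambda tt, yy: jacobian_reduced(yy, params),
                        rtol=1e-10, atol=1e-13)
        if not sol.success:
            raise SettleError(f"integration failed: {sol.message}", y)
        y = sol.y[:, -1]
        if np.max(np.abs(_rhs3(y, params))) < rhs_tol:
            settled = True
            break
        if t >= t_max:
            break
        t = min(2.0 * t, t_max)
    if not settled and np.max(np.abs(_rhs3(y, params))) >= rhs_tol:
        raise SettleError(
            f"no equilibrium within t = {t_max} yr "
            f"(max |rhs| = {np.max(np.abs(_rhs3(y, params))):.3e})", y)
    y = _polish(y, params)
    return MeanFieldState.from_array(y)


def _polish(y, params: ParameterSet) -> np.ndarray:
    if y[0] < 1e-10:  # forest-free: polish inside the GBA subsystem
        sol = root(lambda gb: rhs_gba(gb, params), y[1:3], tol=1e-13)
        if sol.success and np.linalg.norm(sol.x - y[1:3]) < 1e-3:
            return np.array([0.0, sol.x[0], sol.x[1]])
        return np.array([0.0, y[1], y[2]])
    sol = root(lambda x: _rhs3(x, params), y,
               jac=lambda x: jacobian_reduced(x, params), tol=1e-13)
    if sol.success and np.linalg.norm(sol.x - y) < 1e-3:
        return sol.x
    return y
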