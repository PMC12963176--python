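"""Steady states, stability and bifurcation structure of the mean-field model.

The forest-free (GBA) equilibrium is the unique root of

    Phi_G(G) = calF(G) := (1 - G) * (gamma q / (gamma + q)) * (1/G - beta_G/q)

on (0, min(1, q/beta_G)); uniqueness follows because calF is strictly
decreasing there while Phi_G is nondecreasing.  Its stability within the
forest-free boundary always holds; stability against forest invasion is
decided by the sign of the invasion eigenvalue

    lambda_F = phi_G*Gbar + phi_A*Abar - beta_F*Bbar - Phi_F(Gbar) - mu,

the per-capita growth rate of an infinitesimal forest fraction.  Zeros of
lambda_F in a parameter are transcritical branch points (BP) at which a
forest-containing equilibrium branch crosses the forest-free one.  In the
saturated-flammability regime (Gbar well above the percolation threshold,
Phi_F(Gbar) ~ f1) the branch-point locus obeys the closed relation
Bbar = (phi - mu~)/(phi + beta_F) with mu~ = mu + f1, and Bbar expands in
powers of the grassland flammability ceiling g1.

One-parameter branches of forest equilibria are traced by pseudo-arclength
continuation of the reduced (F, G, B) system, with limit points (LP, folds)
flagged where the branch tangent reverses in the parameter and branch points
where it meets the forest-free boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .meanfield import (MeanFieldState, _rhs3, jacobian_reduced, rhs_gba,
                        settle_to_equilibrium, SettleError)
from .params import ParameterSet

__all__ = [
    "GBAEquilibrium",
    "Branch",
    "calF",
    "solve_gba",
    "estimate_gba",
    "gba_jacobian",
    "invasion_eigenvalue",
    "branch_point",
    "saturated_branch_relation",
    "series_branch_locus",
    "continuation_1d",
    "forest_onset_sweep",
    "equilibrium_gb_given_f",
    "transcritical_curvature",
    "mu_asymptotics",
    "fit_linear_regimes",
]

_EIG_MARGIN = 1e-8  # |Re lambda| below this -> flagged marginal, never silently classified


@dataclass(frozen=True)
class GBAEquilibrium:
    """The unique forest-free steady state (G, B, A) with stability info."""

    G: float
    B: float
    A: float
    stable_within_gba: bool
    invasion_eigenvalue: float

    def as_state(self) -> MeanFieldState:
        return MeanFieldState(0.0, self.G, self.B, self.A)


def calF(G, params: ParameterSet):
    """Right-hand side of the scalar steady-state balance for the GBA system."""
    G = np.asarray(G, dtype=float)
    if np.any(G <= 0) or np.any(G >= 1):
        raise ValueError("calF is defined on G in (0, 1)")
    p = params
    out = (1.0 - G) * (p.gamma * p.q / (p.gamma + p.q)) * (1.0 / G - p.beta_G / p.q)
    return out if out.ndim else float(out)


def solve_gba(params: ParameterSet, xtol=1e-12) -> GBAEquilibrium:
    """Locate the unique GBA steady state by bisection.

    The root of ``Phi_G(G) - calF(G)`` is bracketed on
    ``(0, min(1, q/beta_G))``; Bbar then follows from the exact relation
    ``Bbar = [gamma (1-G) - Phi_G(G) G] / (gamma + beta_G G)``.
    """
    p = params
    if p.gamma <= 0 or p.q <= 0 or p.beta_G <= 0:
        raise ValueError("solve_gba requires positive gamma, q and beta_G")
    hi = min(1.0, p.q / p.beta_G)

    def f(G):
        return p.Phi_G(G) - calF(G, p)

    a, b = 1e-14, hi * (1.0 - 1e-14)
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise RuntimeError("failed to bracket the GBA steady state "
                           f"(f({a})={fa:.3g}, f({b})={fb:.3g})")
    Gbar = brentq(f, a, b, xtol=xtol, rtol=8.881784197001252e-16)
    Bbar = (p.gamma * (1.0 - Gbar) - p.Phi_G(Gbar) * Gbar) / (p.gamma + p.beta_G * Gbar)
    Abar = 1.0 - Gbar - Bbar
    eigs = np.linalg.eigvals(gba_jacobian_at(Gbar, Bbar, p))
    lam = _invasion_eigenvalue_at(Gbar, Bbar, Abar, p)
    return GBAEquilibrium(G=Gbar, B=Bbar, A=Abar,
                          stable_within_gba=bool(np.all(eigs.real < 0.0)),
                          invasion_eigenvalue=lam)


def estimate_gba(params: ParameterSet) -> tuple:
    """Timescale-separation estimate of the GBA steady state.

    Valid when fire quenching is slower than fire spread over grass
    (``q < beta_G``) and the regrowth-quenching rate scale dominates the
    flammability ceiling; then ``Gbar ~ q/beta_G`` and the burnt land splits
    between burning and ash in the ratio gamma/q.
    """
    p = params
    if p.q >= p.beta_G:
        raise ValueError("estimate requires q < beta_G")
    G = p.q / p.beta_G
    B = p.gamma * (1.0 - G) / (p.q + p.gamma)
    A = p.q * (1.0 - G) / (p.q + p.gamma)
    return (G, B, A)


def gba_jacobian_at(G, B, params: ParameterSet) -> np.ndarray:
    """2x2 linearisation of the (G, B) subsystem at an arbitrary point."""
    p = params
    PG = p.Phi_G(G)
    z = (G - p.theta_G) / p.s_G
    e = np.exp(-abs(z))
    dPG = (p.g1 - p.g0) / p.s_G * e / (1.0 + e) ** 2
    return np.array([
        [-p.gamma - dPG * G - PG - p.beta_G * B, -p.gamma - p.beta_G * G],
        [dPG * G + PG + p.beta_G * B, -p.q + p.beta_G * G],
    ])


def gba_jacobian(params: ParameterSet) -> np.ndarray:
    """2x2 Jacobian of the forest-free subsystem at the GBA steady state.

    Both eigenvalues have strictly negative real part for any admissible
    parameters (the trace is negative because Gbar < q/beta_G, and the
    determinant is positive because Phi_G' >= 0 > calF' at the root).
    """
    eq = solve_gba(params)
    return gba_jacobian_at(eq.G, eq.B, params)


def _invasion_eigenvalue_at(G, B, A, params: ParameterSet) -> float:
    p = params
    return float(p.phi_G * G + p.phi_A * A - p.beta_F * B - p.Phi_F(G) - p.mu)


def invasion_eigenvalue(params: ParameterSet) -> float:
    """Growth rate of an infinitesimal forest fraction at the GBA equilibrium.

    This is the top-left entry of the full linearisation at F = 0 (the rest of
    that matrix is block-triangular with the always-stable GBA block), so the
    GBA state is stable to forest invasion exactly when the returned value is
    negative.
    """
    eq = solve_gba(params)
    return eq.invasion_eigenvalue


def branch_point(params: ParameterSet, pname: str, bracket) -> float:
    """Root of the invasion eigenvalue in the named parameter (transcritical BP)."""
    a, b = float(bracket[0]), float(bracket[1])

    def lam(value):
        return invasion_eigenvalue(_with(params, pname, value))

    fa, fb = lam(a), lam(b)
    if fa * fb > 0:
        raise ValueError(
            f"invasion eigenvalue does not change sign on [{a}, {b}] "
            f"({fa:.3g}, {fb:.3g})")
    return brentq(lam, a, b, xtol=1e-14, rtol=1e-10)


def _with(params: ParameterSet, pname: str, value) -> ParameterSet:
    if pname == "phi":  # common forest-spread rate phi = phi_G = phi_A
        return params.replace(phi_G=float(value), phi_A=float(value))
    return params.replace(**{pname: float(value)})


def saturated_branch_relation(params: ParameterSet) -> tuple:
    """(Bbar, (phi - mu~)/(phi + beta_F)) with mu~ = mu + f1.

    At a transcritical branch point with the forest flammability saturated
    (Gbar well above theta_F) the two values coincide.  Requires
    phi_G == phi_A.
    """
    p = params
    if p.phi_G != p.phi_A:
        raise ValueError("saturated relation assumes phi_G == phi_A")
    eq = solve_gba(p)
    mu_t = p.mu + p.f1
    return eq.B, (p.phi_G - mu_t) / (p.phi_G + p.beta_F)


def series_branch_locus(params: ParameterSet, order: int):
    """Small-g1 series for the branch-point locus value (phi - mu~)/(phi + beta_F).

    Orders 0..2 of the expansion of the forest-free burning fraction in powers
    of the grass flammability ceiling g1:

        gamma (beta_G - q) / (beta_G (q + gamma))
        + q g1 / (beta_G (beta_G - q))
        + q (q + gamma) g1^2 / ((q - beta_G)^3 gamma)
    """
    p = params
    if p.q >= p.beta_G:
        raise ValueError("series requires q < beta_G")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    total = p.gamma * (p.beta_G - p.q) / (p.beta_G * (p.q + p.gamma))
    if order >= 1:
        total += p.q * p.g1 / (p.beta_G * (p.beta_G - p.q))
    if order >= 2:
        total += p.q * (p.q + p.gamma) * p.g1 ** 2 / ((p.q - p.beta_G) ** 3 * p.gamma)
    return total


# ---------------------------------------------------------------------------
# continuation
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """A one-parameter family of equilibria with stability and bifurcations.

    ``states`` holds the full (F, G, B, A) equilibrium at each parameter
    value; ``max_real_eig`` the largest real part of the reduced Jacobian's
    eigenvalues; ``stable`` the resulting classification (None where the
    leading eigenvalue is within the marginal tolerance of zero);
    ``bifurcations`` a list of (label, parameter_value, state) with label
    "BP" (transcritical) or "LP" (fold).
    """

    pname: str
    values: np.ndarray
    states: np.ndarray
    max_real_eig: np.ndarray
    stable: list
    bifurcations: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.states = np.asarray(self.states, dtype=float)

    def __len__(self):
        return self.values.size


def _stability(x3, params: ParameterSet):
    eigs = np.linalg.eigvals(jacobian_reduced(x3, params))
    m = float(np.max(eigs.real))
    if abs(m) < _EIG_MARGIN:
        return m, None  # marginal
    return m, bool(m < 0)


def _newton_eq(x3, params: ParameterSet, tol=1e-12, maxit=30):
    x = np.array(x3, dtype=float)
    for _ in range(maxit):
        r = _rhs3(x, params)
        if np.max(np.abs(r)) < tol:
            return x, True
        try:
            dx = np.linalg.solve(jacobian_reduced(x, params), -r)
        except np.linalg.LinAlgError:
            return x, False
        if not np.all(np.isfinite(dx)) or np.linalg.norm(dx) > 1.0:
            return x, False
        x = x + dx
    return x, np.max(np.abs(_rhs3(x, params))) < 1e-9


def _extended_newton(y, params, pname, y_pred, tangent, tol=1e-11, maxit=25):
    """Newton on [rhs3; arclength constraint] in y = (F, G, B, p)."""
    y = np.array(y, dtype=float)
    for _ in range(maxit):
        try:
            pset = _with(params, pname, y[3])
        except ValueError:  # stepped outside the parameter's validity domain
            return y, False
        r = np.empty(4)
        r[:3] = _rhs3(y[:3], pset)
        r[3] = tangent @ (y - y_pred)
        if np.max(np.abs(r)) < tol:
            return y, True
        J = np.zeros((4, 4))
        J[:3, :3] = jacobian_reduced(y[:3], pset)
        h = max(1e-7, 1e-7 * abs(y[3]))
        try:
            J[:3, 3] = (_rhs3(y[:3], _with(params, pname, y[3] + h)) -
                        _rhs3(y[:3], _with(params, pname, y[3] - h))) / (2 * h)
        except ValueError:
            J[:3, 3] = (_rhs3(y[:3], _with(params, pname, y[3] + h)) -
                        r[:3]) / h
        J[3, :] = tangent
        try:
            dy = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return y, False
        if not np.all(np.isfinite(dy)):
            return y, False
        y = y + dy
    return y, False


def _trivial_branch(params, pname, values):
    """The forest-free branch F = 0, exact for every parameter value."""
    states, eigmax, stable, bifs = [], [], [], []
    lams = []
    for v in values:
        pset = _with(params, pname, v)
        eq = solve_gba(pset)
        x3 = np.array([0.0, eq.G, eq.B])
        m, st = _stability(x3, pset)
        states.append([0.0, eq.G, eq.B, eq.A])
        eigmax.append(m)
        stable.append(st)
        lams.append(eq.invasion_eigenvalue)
    lams = np.asarray(lams)
    for i in range(len(values) - 1):
        if lams[i] == 0.0 or lams[i] * lams[i + 1] < 0:
            v_bp = branch_point(params, pname, (values[i], values[i + 1]))
            eq = solve_gba(_with(params, pname, v_bp))
            bifs.append(("BP", float(v_bp), np.array([0.0, eq.G, eq.B, eq.A])))
    return Branch(pname=pname, values=np.asarray(values, dtype=float),
                  states=np.asarray(states), max_real_eig=np.asarray(eigmax),
                  stable=stable, bifurcations=bifs)


def _find_forest_seed(params, pname, values):
    """A forest-containing equilibrium somewhere on the parameter grid."""
    for v in list(values[::max(1, len(values) // 12)]) + [values[0], values[-1]]:
        pset = _with(params, pname, v)
        for x0 in ((0.9, 0.05, 0.001), (0.5, 0.3, 0.01)):
            x, ok = _newton_eq(np.array(x0), pset)
            if ok and x[0] > 1e-6 and np.all(x > -1e-9) and x.sum() < 1 + 1e-9:
                return float(v), x
        try:
            st = settle_to_equilibrium((0.9, 0.09, 0.0, 0.01), pset)
        except SettleError:
            continue
        if st.F > 1e-6:
            return float(v), np.array([st.F, st.G, st.B])
    return None


def continuation_1d(params: ParameterSet, pname: str, prange, step,
                    max_points=4000) -> list:
    """Trace equilibrium branches over ``prange`` = (lo, hi).

    Returns a list of :class:`Branch`: the exact forest-free branch on a
    uniform grid (with BPs located by bisection of the invasion eigenvalue)
    and, when present, the forest branch traced by pseudo-arclength
    continuation with adaptive steps.  Folds (LP) are flagged where the
    parameter component of the branch tangent changes sign; stability comes
    from the reduced Jacobian's eigenvalues.
    """
    lo, hi = float(prange[0]), float(prange[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("prange must be a finite increasing interval")
    grid = np.arange(lo, hi + 0.5 * step, step)
    branches = [_trivial_branch(params, pname, grid)]
    seed = _find_forest_seed(params, pname, grid)
    if seed is None:
        return branches
    v0, x0 = seed
    bifs = []
    p_scale = max(abs(hi - lo), 1e-12)
    scale = np.array([1.0, 1.0, 1.0, p_scale])

    def trace(direction):
        """Pseudo-arclength walk from the seed; returns rows (F, G, B, p)."""
        rows = [np.append(x0, v0)]
        tangent = np.array([0.0, 0.0, 0.0, direction])
        ds0 = min(max(2.0 * step / p_scale, 1e-4), 0.05)
        ds = ds0
        n_fail = 0
        while len(rows) < max_points:
            y = rows[-1]
            t_sc = tangent / scale
            t_sc /= np.linalg.norm(t_sc)
            y_pred = y + t_sc * scale * ds
            y_new, ok = _extended_newton(y_pred, params, pname, y_pred,
                                         t_sc / scale, maxit=25)
            if not ok:
                ds *= 0.5
                n_fail += 1
                if ds < 1e-9 or n_fail > 60:
                    break
                continue
            n_fail = 0
            new_tan = y_new - y
            if len(rows) >= 2:
                prev_dp = y[3] - rows[-2][3]
                if prev_dp * new_tan[3] < 0:  # fold in the parameter
                    bifs.append(("LP", float(y[3]),
                                 np.append(y[:3], 1 - y[:3].sum())))
            if y_new[0] < 0:  # crossed the forest-free boundary
                frac = y[0] / (y[0] - y_new[0])
                y_bp = y + frac * (y_new - y)
                v_bp = float(y_bp[3])
                try:  # refine: the crossing coincides with the invasion BP
                    a, b = sorted((float(y[3]), float(y_new[3])))
                    if b > a:
                        v_bp = branch_point(params, pname, (a, b))
                except ValueError:
                    pass
                eq = solve_gba(_with(params, pname, v_bp))
                bifs.append(("BP", v_bp,
                             np.array([0.0, eq.G, eq.B, eq.A])))
                break
            rows.append(y_new)
            tangent = new_tan
            ds = min(ds * 1.3, 4 * ds0)
            if not (lo - 0.05 * p_scale <= y_new[3] <= hi + 0.05 * p_scale):
                break
        return rows

    fwd = trace(+1.0)
    bwd = trace(-1.0)
    rows = np.asarray(bwd[::-1] + fwd[1:])
    values = rows[:, 3]
    states = np.column_stack([rows[:, :3], 1.0 - rows[:, :3].sum(axis=1)])
    eigm, stbl = [], []
    for r in rows:
        m, st = _stability(r[:3], _with(params, pname, r[3]))
        eigm.append(m)
        stbl.append(st)
    branches.append(Branch(pname=pname, values=values, states=states,
                           max_real_eig=np.asarray(eigm), stable=stbl,
                           bifurcations=bifs))
    return branches


def forest_onset_sweep(params: ParameterSet, pname: str, grid,
                       x0=(0.01, 0.99, 0.0, 0.0), takeover=0.5) -> dict:
    """Settle the ODE from a low-forest state at each grid value.

    Returns a dict with the grid, the settled (F, G, B, A) rows, and
    ``threshold``: the smallest grid value whose settled forest fraction
    exceeds ``takeover`` (None if never).
    """
    grid = np.asarray(grid, dtype=float)
    rows = np.empty((grid.size, 4))
    for i, v in enumerate(grid):
        st = settle_to_equilibrium(x0, _with(params, pname, v))
        rows[i] = st.as_array()
    above = np.nonzero(rows[:, 0] > takeover)[0]
    threshold = float(grid[above[0]]) if above.size else None
    return {"pname": pname, "values": grid, "states": rows,
            "threshold": threshold}


def equilibrium_gb_given_f(F, params: ParameterSet, guess=None) -> np.ndarray:
    """Solve the (G, B) equilibrium conditions at a prescribed forest cover F.

    Sets dG = dB = 0 in the reduced system with F held fixed; used to
    evaluate the equilibrium burning response Bbar(F) near the forest-free
    boundary (e.g. for transcritical genericity checks).
    """
    if guess is None:
        eq = solve_gba(params)
        x = np.array([eq.G, eq.B])
    else:
        x = np.array(guess, dtype=float)
    for _ in range(60):
        r = _rhs3(np.array([F, x[0], x[1]]), params)[1:]
        if np.max(np.abs(r)) < 1e-13:
            break
        J = jacobian_reduced(np.array([F, x[0], x[1]]), params)[1:, 1:]
        x = x + np.linalg.solve(J, -r)
    return x


def transcritical_curvature(params: ParameterSet, h=1e-5) -> float:
    """Q''(0) = -2 Bbar'(0) (phi + beta_F) - 2 phi, the genericity quantity.

    ``Bbar'(0)`` is obtained by one-sided finite differences of the
    equilibrium burning fraction along the fixed-F equilibrium family.
    Nonzero curvature certifies a nondegenerate transcritical crossing.
    """
    p = params
    if p.phi_G != p.phi_A:
        raise ValueError("transcritical analysis assumes phi_G == phi_A")
    b0 = equilibrium_gb_given_f(0.0, p)[1]
    b1 = equilibrium_gb_given_f(h, p)[1]
    b2 = equilibrium_gb_given_f(2 * h, p)[1]
    dB = (-3 * b0 + 4 * b1 - b2) / (2 * h)
    return float(-2.0 * dB * (p.phi_G + p.beta_F) - 2.0 * p.phi_G)


def mu_asymptotics(params: ParameterSet):
    """Closed-form linear regimes of the forest branch in the mortality rate.

    The exact coefficients of the two linear regimes (near F = 0 and near
    F = 1) are not built in; use :func:`fit_linear_regimes` on a continued
    branch for an empirical characterisation.
    """
    raise NotImplementedError(
        "closed-form mortality asymptotics are not available; "
        "fit_linear_regimes() provides an empirical alternative")


def fit_linear_regimes(branch: Branch, low_band=(0.0, 0.15),
                       high_band=(0.85, 1.0)) -> dict:
    """Least-squares lines through the near-F=0 and near-F=1 branch regimes.

    Returns ``{"low": (slope, intercept), "high": (slope, intercept)}`` for
    F as a function of the branch parameter, fitted over the requested forest
    cover bands.  Raises if a band contains fewer than three branch points.
    """
    F = branch.states[:, 0]
    out = {}
    for key, (a, b) in (("low", low_band), ("high", high_band)):
        m = (F >= a) & (F <= b) & (F > 1e-12)
        if m.sum() < 3:
            raise ValueError(f"too few branch points with F in [{a}, {b}]")
        coef = np.polyfit(branch.values[m], F[m], 1)
        out[key] = (float(coef[0]), float(coef[1]))
    return out
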