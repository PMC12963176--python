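"""Spatial mean-field FGBA dynamics: nonlocal reaction equations on a grid.

In the many-site limit the landscape is described by four density fields
F(r,t), G(r,t), B(r,t), A(r,t) on the periodic square, coupled through
Gaussian-kernel convolutions:

    dF/dt = (phi_G G + phi_A A) (W_F*F) - mu F - beta_F F (W_B*B)
            - Phi_F(W_G*G) F
    dG/dt = gamma A - phi_G G (W_F*F) + mu F - Phi_G(W_G*G) G
            - beta_G G (W_B*B)
    dB/dt = Phi_F(W_G*G) F + Phi_G(W_G*G) G - q B
            + (beta_G G + beta_F F) (W_B*B)
    dA/dt = q B - gamma A - phi_A A (W_F*F)

where ``*`` is convolution over the torus.  The flammability sigmoids act on
the smoothed grass field, so spatially uniform data reduce the system exactly
to the nonspatial ODE model.  Fields are discretised on an n x n grid and the
convolutions evaluated as circular convolutions via the FFT with the kernel
sampled at minimal-image distances and renormalised to unit discrete mass
(constants are then exact fixed points of the convolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .meanfield import rhs_fgba
from .params import ParameterSet

__all__ = ["FieldState", "periodic_convolve", "rhs_ide", "integrate_ide"]

_kernel_cache: dict = {}


@dataclass
class FieldState:
    """Four n x n cover-density grids on the uniform periodic mesh of [0, L)^2."""

    F: np.ndarray
    G: np.ndarray
    B: np.ndarray
    A: np.ndarray
    L: float = 1.0

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=float) for a in (self.F, self.G, self.B, self.A)]
        self.F, self.G, self.B, self.A = arrs
        n = self.F.shape
        if any(a.shape != n for a in arrs) or self.F.ndim != 2 \
                or n[0] != n[1]:
            raise ValueError("fields must share one square n x n shape")

    @classmethod
    def uniform(cls, fracs, n, L=1.0) -> "FieldState":
        F, G, B, A = [np.full((n, n), float(v)) for v in fracs]
        return cls(F, G, B, A, L=L)

    @property
    def n(self) -> int:
        return self.F.shape[0]

    def validate(self, tol=1e-8) -> None:
        for a in (self.F, self.G, self.B, self.A):
            if np.any(a < -tol) or np.any(a > 1 + tol):
                raise ValueError("field values must lie in [0, 1]")
        if np.max(np.abs(self.F + self.G + self.B + self.A - 1.0)) > tol:
            raise ValueError("fields must sum to one pointwise")

    def means(self) -> np.ndarray:
        return np.array([self.F.mean(), self.G.mean(), self.B.mean(),
                         self.A.mean()])


def _torus_kernel_fft(n, sigma, L):
    """FFT of the unit-mass Gaussian kernel sampled on the n x n torus mesh."""
    key = (n, float(sigma), float(L))
    if key not in _kernel_cache:
        x = np.arange(n) * (L / n)
        d = np.minimum(x, L - x)  # minimal-image axis distances from 0
        d2 = d[:, None] ** 2 + d[None, :] ** 2
        k = np.exp(-d2 / (2.0 * sigma * sigma))
        k /= k.sum()
        _kernel_cache[key] = np.fft.rfft2(k)
    return _kernel_cache[key]


def periodic_convolve(field, sigma, L=1.0) -> np.ndarray:
    """Circular convolution of an n x n field with the torus Gaussian kernel.

    The discrete kernel has unit mass, so constant fields are exact fixed
    points and the total mass of the field is preserved to round-off.
    """
    field = np.asarray(field, dtype=float)
    n = field.shape[0]
    if field.ndim != 2 or field.shape[1] != n:
        raise ValueError("field must be square")
    if n < 8:
        raise ValueError("grid too coarse (need n >= 8)")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    kf = _torus_kernel_fft(n, sigma, L)
    return np.fft.irfft2(np.fft.rfft2(field) * kf, s=(n, n))


def rhs_ide(fields: FieldState, params: ParameterSet) -> tuple:
    """Pointwise time derivatives (dF, dG, dB, dA); they sum to zero exactly."""
    p = params
    F, G, B, A = fields.F, fields.G, fields.B, fields.A
    L = fields.L
    cF = periodic_convolve(F, p.sigma_F, L)
    cB = periodic_convolve(B, p.sigma_B, L)
    cG = periodic_convolve(G, p.sigma_G, L)
    PF = p.Phi_F(cG)
    PG = p.Phi_G(cG)
    dF = (p.phi_G * G + p.phi_A * A) * cF - p.mu * F - p.beta_F * F * cB - PF * F
    dG = p.gamma * A - p.phi_G * G * cF + p.mu * F - PG * G - p.beta_G * G * cB
    dB = PF * F + PG * G - p.q * B + (p.beta_G * G + p.beta_F * F) * cB
    dA = p.q * B - p.gamma * A - p.phi_A * A * cF
    return dF, dG, dB, dA


def integrate_ide(fields0: FieldState, params: ParameterSet, t_end,
                  tol=1e-8, t_eval=None, method="RK45") -> list:
    """Method-of-lines integration; returns ``[(t, FieldState), ...]``.

    F, G and B are integrated and A closed as 1 - F - G - B, so the pointwise
    cover sum is conserved by construction.  Spatially uniform initial data
    reproduce the nonspatial ODE trajectory at every grid point (the
    convolution of a constant is the same constant).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    fields0.validate(tol=1e-6)
    n = fields0.n
    L = fields0.L
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 11)

    def unpack(y):
        F, G, B = y.reshape(3, n, n)
        return FieldState(F, G, B, np.clip(1.0 - F - G - B, 0.0, 1.0), L=L)

    def f(t, y):
        F, G, B = y.reshape(3, n, n)
        A = 1.0 - F - G - B
        dF, dG, dB, _ = rhs_ide(FieldState(F, G, B, A, L=L), params)
        return np.concatenate([dF.ravel(), dG.ravel(), dB.ravel()])

    y0 = np.concatenate([fields0.F.ravel(), fields0.G.ravel(),
                         fields0.B.ravel()])
    sol = solve_ivp(f, (0.0, float(t_end)), y0, method=method,
                    t_eval=np.asarray(t_eval, dtype=float),
                    rtol=tol, atol=tol * 1e-2)
    if not sol.success:
        raise RuntimeError(f"IDE integration failed: {sol.message}")
    return [(float(t), unpack(sol.y[:, k])) for k, t in enumerate(sol.t)]
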