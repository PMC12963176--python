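"""Model parameters, domain geometry, spreading kernels and flammability sigmoids.

The FGBA model describes a landscape of ``N`` vegetation sites scattered
uniformly on a periodic square of side ``L``.  Each site is in one of four
states -- forest (F), grass (G), burning (B) or ash (A) -- and transitions
between them at rates controlled by the :class:`ParameterSet` below.  Spatial
interactions (seed dispersal, fire spread, fuel connectivity) are mediated by
isotropic Gaussian kernels; the percolation-like onset of large fires is
encoded by sigmoidal flammability functions of the local grass cover.

All rates are in 1/yr; lengths are in units of the domain side unless noted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "Domain",
    "SiteSet",
    "flammability",
    "periodic_distance",
    "kernel_value",
    "sample_sites",
    "sigma_from_spacings",
]

_TWO_PI = 2.0 * math.pi


def flammability(x, lo, hi, theta, s):
    """Sigmoidal flammability ``lo + (hi-lo)/(1+exp(-(x-theta)/s))``.

    Parameters
    ----------
    x : array_like
        Local (kernel-weighted) grass cover; must be finite.
    lo, hi : float
        Floor/ceiling spontaneous ignition rates (1/yr).  ``lo`` is the rate
        with no grass in the neighbourhood, ``hi`` the rate in pure grassland.
    theta : float
        Percolation threshold: the cover fraction at which flammability is
        halfway between ``lo`` and ``hi``.
    s : float
        Sigmoid width; the transition happens over a few multiples of ``s``.

    Returns
    -------
    Ignition rate(s) in 1/yr, bounded by ``[lo, hi]`` and monotone
    nondecreasing in ``x`` when ``hi >= lo``.
    """
    if s <= 0:
        raise ValueError("sigmoid width s must be > 0")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("flammability argument must be finite")
    # numerically stable logistic
    z = (x - theta) / s
    out = lo + (hi - lo) * _expit(z)
    return out if out.ndim else float(out)


def _expit(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def periodic_distance(r, s, L):
    """Minimal-image Euclidean distance between points on the L-periodic torus.

    ``r`` and ``s`` are 2-vectors or arrays of shape (..., 2).  The result is
    symmetric, satisfies the triangle inequality and is at most ``L/sqrt(2)``.
    """
    if L <= 0:
        raise ValueError("domain side L must be > 0")
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(s))):
        raise ValueError("coordinates must be finite")
    d = r - s
    d -= L * np.round(d / L)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return out if np.ndim(out) else float(out)


def kernel_value(r_j, r_i, sigma, L, exact_torus=False, n_images=3):
    """Gaussian spreading kernel ``W(r_j, r_i)`` on the periodic domain.

    The kernel carries the continuum normalisation ``1/(2 pi sigma^2)`` so that
    its integral over the plane is one; on the torus the wrap-around images
    are negligible for ``sigma <= L/8`` (relative error < 1e-7).  Set
    ``exact_torus=True`` to sum over periodic images for wide kernels.
    """
    if sigma <= 0:
        raise ValueError("kernel width sigma must be > 0")
    norm = 1.0 / (_TWO_PI * sigma * sigma)
    if not exact_torus:
        d = periodic_distance(r_j, r_i, L)
        return norm * np.exp(-np.square(d) / (2.0 * sigma * sigma))
    r = np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float)
    total = 0.0
    ks = np.arange(-n_images, n_images + 1)
    for kx in ks:
        for ky in ks:
            dx = r[..., 0] + kx * L
            dy = r[..., 1] + ky * L
            total = total + np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
    out = norm * total
    return out if np.ndim(out) else float(out)


def sample_sites(N, L, seed):
    """Draw ``N`` site positions uniformly on ``[0, L)^2`` (seeded, reproducible)."""
    if N < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    return SiteSet(positions=rng.uniform(0.0, L, size=(int(N), 2)), L=float(L))


def sigma_from_spacings(n_spacings, L, N):
    """Convert a kernel width given in mean-spacing units to domain-length units.

    The mean spacing of ``N`` uniform sites on an ``L x L`` square is
    ``dx = L/sqrt(N)``; this returns ``n_spacings * dx``.
    """
    return float(n_spacings) * float(L) / math.sqrt(N)


@dataclass(frozen=True)
class Domain:
    """Periodic square domain of side ``L``."""

    L: float = 1.0

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("domain side L must be > 0")

    @property
    def area(self) -> float:
        return self.L * self.L


@dataclass
class SiteSet:
    """Positions of the ``N`` vegetation sites inside the domain."""

    positions: np.ndarray
    L: float = 1.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if np.any(self.positions < 0) or np.any(self.positions >= self.L):
            raise ValueError("all coordinates must lie in [0, L)")

    def __len__(self) -> int:
        return self.positions.shape[0]


# Table-like defaults: representative rate magnitudes for a ~1 m site spacing.
# Fire processes (beta_G, beta_F, q) are orders of magnitude faster than grass
# regrowth (gamma), which is in turn much faster than forest processes
# (phi_G, phi_A, mu) and spontaneous ignition floors (f0, g0).
_DEFAULTS = dict(
    beta_G=1e5,
    beta_F=1e4,
    q=1e4,
    gamma=1e2,
    phi_G=1.0,
    phi_A=1.0,
    mu=1e-2,
    f0=1e-2,
    f1=1e-1,
    g0=1e-2,
    g1=1e-1,
    theta_F=0.6,
    theta_G=0.6,
    s_F=0.05,
    s_G=0.05,
    L=1.0,
    N=2000,
)

_RATE_FIELDS = ("beta_G", "beta_F", "q", "gamma", "phi_G", "phi_A", "mu",
                "f0", "f1", "g0", "g1")


@dataclass(frozen=True)
class ParameterSet:
    """Validated container for every FGBA model parameter.

    Rates (1/yr): ``beta_G``/``beta_F`` fire spread over grass/forest, ``q``
    quenching, ``gamma`` grass regrowth from ash, ``phi_G``/``phi_A`` forest
    seeding into grass/ash, ``mu`` non-fire tree mortality, ``f0..g1`` the
    flammability sigmoid floors/ceilings for forest and grass sites.
    Dimensionless: percolation thresholds ``theta_F``/``theta_G`` and sigmoid
    widths ``s_F``/``s_G``.  Geometry: kernel widths ``sigma_F``/``sigma_B``/
    ``sigma_G`` in domain-length units (default: five mean site spacings),
    domain side ``L`` and site count ``N``.
    """

    beta_G: float = _DEFAULTS["beta_G"]
    beta_F: float = _DEFAULTS["beta_F"]
    q: float = _DEFAULTS["q"]
    gamma: float = _DEFAULTS["gamma"]
    phi_G: float = _DEFAULTS["phi_G"]
    phi_A: float = _DEFAULTS["phi_A"]
    mu: float = _DEFAULTS["mu"]
    f0: float = _DEFAULTS["f0"]
    f1: float = _DEFAULTS["f1"]
    g0: float = _DEFAULTS["g0"]
    g1: float = _DEFAULTS["g1"]
    theta_F: float = _DEFAULTS["theta_F"]
    theta_G: float = _DEFAULTS["theta_G"]
    s_F: float = _DEFAULTS["s_F"]
    s_G: float = _DEFAULTS["s_G"]
    sigma_F: float | None = None
    sigma_B: float | None = None
    sigma_G: float | None = None
    L: float = _DEFAULTS["L"]
    N: int = _DEFAULTS["N"]

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        default_sigma = sigma_from_spacings(5.0, self.L, self.N)
        for name in ("sigma_F", "sigma_B", "sigma_G"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, default_sigma)
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        for name in ("theta_F", "theta_G"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("s_F", "s_G", "sigma_F", "sigma_B", "sigma_G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.f1 < self.f0:
            raise ValueError("f1 must be >= f0")
        if self.g1 < self.g0:
            raise ValueError("g1 must be >= g0")

    # -- derived quantities -------------------------------------------------
    @property
    def delta_x(self) -> float:
        """Mean site spacing L/sqrt(N)."""
        return self.L / math.sqrt(self.N)

    @property
    def domain(self) -> Domain:
        return Domain(L=self.L)

    def Phi_F(self, x):
        """Forest-site flammability as a function of local grass cover."""
        return flammability(x, self.f0, self.f1, self.theta_F, self.s_F)

    def Phi_G(self, x):
        """Grass-site flammability as a function of local grass cover."""
        return flammability(x, self.g0, self.g1, self.theta_G, self.s_G)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["N"] = int(d["N"])
        return d

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = set(cls.field_names())
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}")
        return cls(**{k: (int(v) if k == "N" else float(v))
                      for k, v in d.items()})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must be a flat key-value mapping")
        return cls.from_dict(data)

    def missing_from(self, d: dict) -> Iterator[str]:
        for name in self.field_names():
            if name not in d:
                yield name
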