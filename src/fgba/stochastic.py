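"""Event-driven (Gillespie) simulation of the spatial stochastic FGBA process.

Each of the ``N`` sites carries a state in {F, G, B, A} and jumps at
exponential rates built from three kernel-weighted local fields

    wF_i = (1/N) sum_j W_F(r_i, r_j) [site j is forest]      (seed pressure)
    wB_i = (1/N) sum_j W_B(r_i, r_j) [site j is burning]     (fire exposure)
    wG_i = (1/N) sum_j W_G(r_i, r_j) [site j is grass]       (fuel connectivity)

with the focal site excluded from its own sums.  The per-site transition
rates are

    G -> F : phi_G * wF          F -> B : beta_F * wB + Phi_F(wG)
    A -> F : phi_A * wF          G -> B : beta_G * wB + Phi_G(wG)
    F -> G : mu                  B -> A : q
    A -> G : gamma

The simulation is an exact stochastic simulation algorithm (direct method):
waiting times are exponential in the total rate, events are chosen
proportionally to their rates via a Fenwick (binary-indexed) tree, and after
each event only the sites within the kernel truncation radius (4 sigma) of
the flipped site have their fields and rates updated -- an O(neighbourhood)
update that is numerically identical to full recomputation.

A uniform-kernel mode (W == 1) replaces the per-site bookkeeping by an exact
count-based SSA over the four state counts; all sites in a state class then
share one rate, so the aggregated chain is the same Markov process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .params import ParameterSet, SiteSet, kernel_value
from .trajectory import Trajectory

__all__ = [
    "STATE_LABELS",
    "Configuration",
    "SpatialKernels",
    "site_rates",
    "gillespie_run",
    "cover_fractions",
    "make_initial_configuration",
]

STATE_LABELS = "FGBA"
_F, _G, _B, _A = 0, 1, 2, 3
_TRUNC_SIGMAS = 4.0  # kernel truncation radius for neighbour lists
_REBUILD_EVERY = 1 << 23  # periodic from-scratch refresh of fields/rates


def state_codes(labels) -> np.ndarray:
    return np.array([STATE_LABELS.index(c) for c in labels], dtype=np.int8)


class SpatialKernels:
    """Truncated neighbour lists (CSR) for the three spreading kernels.

    ``kernel`` maps (distances, sigma) to kernel values and defaults to the
    normalised Gaussian; alternative isotropic kernels can be plugged in
    (``trunc_radius`` then sets the cutoff in multiples of sigma).
    """

    def __init__(self, sites: SiteSet, params: ParameterSet,
                 kernel=None, trunc_radius=_TRUNC_SIGMAS):
        self.sites = sites
        kernel = kernel or kernel_value_from_distance
        N = len(sites)
        L = sites.L
        tree = cKDTree(sites.positions, boxsize=L)
        self.csr = {}
        for name, sigma in (("F", params.sigma_F), ("B", params.sigma_B),
                            ("G", params.sigma_G)):
            r = min(trunc_radius * sigma, 0.499 * L)
            pairs = tree.query_pairs(r=r, output_type="ndarray")
            if pairs.size:
                d = _torus_dist(sites.positions[pairs[:, 0]],
                                sites.positions[pairs[:, 1]], L)
                w = kernel(d, sigma) / N
                rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
                cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
                data = np.concatenate([w, w])
            else:
                rows = cols = np.empty(0, dtype=np.int64)
                data = np.empty(0)
            m = csr_matrix((data, (rows, cols)), shape=(N, N))
            m.sum_duplicates()
            self.csr[name] = m

    def field(self, name: str, indicator: np.ndarray) -> np.ndarray:
        return self.csr[name] @ indicator.astype(float)


def _torus_dist(a, b, L):
    d = a - b
    d -= L * np.round(d / L)
    return np.sqrt(np.sum(d * d, axis=-1))


def kernel_value_from_distance(d, sigma):
    return np.exp(-np.square(d) / (2.0 * sigma * sigma)) / (2.0 * np.pi * sigma * sigma)


@dataclass
class Configuration:
    """Site positions, per-site states and cached kernel-weighted fields."""

    sites: SiteSet
    states: np.ndarray
    kernels: SpatialKernels | None = None
    wF: np.ndarray | None = None
    wB: np.ndarray | None = None
    wG: np.ndarray | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.sites),):
            raise ValueError("states must have one entry per site")
        if self.states.min() < 0 or self.states.max() > 3:
            raise ValueError("states must be codes 0..3 (F, G, B, A)")

    def ensure_fields(self, params: ParameterSet) -> None:
        if self.kernels is None:
            self.kernels = SpatialKernels(self.sites, params)
        self.recompute_fields()

    def recompute_fields(self) -> None:
        if self.kernels is None:
            raise ValueError("kernels not built; call ensure_fields(params)")
        self.wF = self.kernels.field("F", self.states == _F)
        self.wB = self.kernels.field("B", self.states == _B)
        self.wG = self.kernels.field("G", self.states == _G)

    def cache_error(self) -> float:
        """Max absolute deviation of cached fields from full recomputation."""
        if self.kernels is None or self.wF is None:
            return 0.0
        err = 0.0
        for cached, name, code in ((self.wF, "F", _F), (self.wB, "B", _B),
                                   (self.wG, "G", _G)):
            exact = self.kernels.field(name, self.states == code)
            err = max(err, float(np.max(np.abs(cached - exact), initial=0.0)))
        return err

    def counts(self) -> np.ndarray:
        return np.bincount(self.states, minlength=4)

    def copy(self) -> "Configuration":
        return Configuration(sites=self.sites, states=self.states.copy(),
                             kernels=self.kernels,
                             wF=None if self.wF is None else self.wF.copy(),
                             wB=None if self.wB is None else self.wB.copy(),
                             wG=None if self.wG is None else self.wG.copy())


def cover_fractions(config: Configuration) -> tuple:
    """Fractions of sites in each of the four states (F, G, B, A)."""
    c = config.counts()
    n = c.sum()
    return tuple(float(x) / n for x in c)


def make_initial_configuration(siteset: SiteSet, spec, seed,
                               params: ParameterSet | None = None) -> Configuration:
    """Assign initial states either by seeded random fractions or by a mask.

    ``spec`` is either a mapping like ``{"F": 0.4, "G": 0.6}`` (fractions
    summing to one; counts are rounded to nearest and any remainder goes to
    grass, then states are assigned by a seeded shuffle) or a tuple
    ``(mask_fn, inside_label, outside_label)`` where ``mask_fn(positions)``
    returns a boolean array (geometric initial conditions such as a forest
    block for fire-front experiments).
    """
    N = len(siteset)
    if isinstance(spec, dict):
        fr = {k: float(v) for k, v in spec.items()}
        if any(k not in STATE_LABELS for k in fr):
            raise ValueError("state labels must be among F, G, B, A")
        if any(v < 0 for v in fr.values()) or abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        counts = {k: int(round(v * N)) for k, v in fr.items()}
        counts["G"] = counts.get("G", 0) + (N - sum(counts.values()))
        if counts["G"] < 0:
            raise ValueError("rounded counts exceed the number of sites")
        states = np.concatenate([
            np.full(counts.get(lab, 0), code, dtype=np.int8)
            for code, lab in enumerate(STATE_LABELS)])
        rng = np.random.default_rng(seed)
        rng.shuffle(states)
    else:
        mask_fn, inside, outside = spec
        mask = np.asarray(mask_fn(siteset.positions), dtype=bool)
        states = np.where(mask, STATE_LABELS.index(inside),
                          STATE_LABELS.index(outside)).astype(np.int8)
    config = Configuration(sites=siteset, states=states)
    if params is not None:
        config.ensure_fields(params)
    return config


def site_rates(config: Configuration, i: int, params: ParameterSet) -> dict:
    """Per-transition rates (1/yr) of site ``i`` given the cached fields."""
    if config.wF is None:
        config.ensure_fields(params)
    p = params
    st = int(config.states[i])
    wF, wB, wG = float(config.wF[i]), float(config.wB[i]), float(config.wG[i])
    if st == _F:
        return {"F->B": p.beta_F * wB + float(p.Phi_F(wG)), "F->G": p.mu}
    if st == _G:
        return {"G->F": p.phi_G * wF,
                "G->B": p.beta_G * wB + float(p.Phi_G(wG))}
    if st == _B:
        return {"B->A": p.q}
    return {"A->F": p.phi_A * wF, "A->G": p.gamma}


# ---------------------------------------------------------------------------
# numba core
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sig_rate(x, lo, hi, theta, s):
    z = (x - theta) / s
    if z >= 0.0:
        return lo + (hi - lo) / (1.0 + np.exp(-z))
    e = np.exp(z)
    return lo + (hi - lo) * e / (1.0 + e)


@njit(cache=True, inline="always")
def _rate_of(st, wf, wb, wg, bG, bF, q, gam, phG, phA, mu,
             f0, f1, thF, sF, g0, g1, thG, sG):
    if st == 0:
        return bF * wb + _sig_rate(wg, f0, f1, thF, sF) + mu
    elif st == 1:
        return phG * wf + bG * wb + _sig_rate(wg, g0, g1, thG, sG)
    elif st == 2:
        return q
    return phA * wf + gam


@njit(cache=True)
def _fen_add(tree, i, delta):
    i += 1
    n = tree.shape[0] - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fen_total(tree):
    n = tree.shape[0] - 1
    s = 0.0
    i = n
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=True)
def _fen_find(tree, u):
    n = tree.shape[0] - 1
    bit = 1
    while (bit << 1) <= n:
        bit <<= 1
    idx = 0
    while bit > 0:
        nxt = idx + bit
        if nxt <= n and tree[nxt] <= u:
            u -= tree[nxt]
            idx = nxt
        bit >>= 1
    if idx >= n:
        idx = n - 1
    return idx


@njit(cache=True)
def _refresh(states, iF, jF, vF, iB, jB, vB, iG, jG, vG, wF, wB, wG,
             rates, tree, bG, bF, q, gam, phG, phA, mu,
             f0, f1, thF, sF, g0, g1, thG, sG):
    N = states.shape[0]
    wF[:] = 0.0
    wB[:] = 0.0
    wG[:] = 0.0
    for i in range(N):
        st = states[i]
        if st == 0:
            for k in range(iF[i], iF[i + 1]):
                wF[jF[k]] += vF[k]
        elif st == 1:
            for k in range(iG[i], iG[i + 1]):
                wG[jG[k]] += vG[k]
        elif st == 2:
            for k in range(iB[i], iB[i + 1]):
                wB[jB[k]] += vB[k]
    tree[:] = 0.0
    for i in range(N):
        rates[i] = _rate_of(states[i], wF[i], wB[i], wG[i], bG, bF, q, gam,
                            phG, phA, mu, f0, f1, thF, sF, g0, g1, thG, sG)
        _fen_add(tree, i, rates[i])


@njit(cache=True)
def _touch(i, wF, wB, wG, states, rates, tree, bG, bF, q, gam, phG, phA, mu,
           f0, f1, thF, sF, g0, g1, thG, sG):
    r_new = _rate_of(states[i], wF[i], wB[i], wG[i], bG, bF, q, gam,
                     phG, phA, mu, f0, f1, thF, sF, g0, g1, thG, sG)
    _fen_add(tree, i, r_new - rates[i])
    rates[i] = r_new


@njit(cache=True)
def _run_spatial(states, iF, jF, vF, iB, jB, vB, iG, jG, vG,
                 wF, wB, wG,
                 bG, bF, q, gam, phG, phA, mu,
                 f0, f1, thF, sF, g0, g1, thG, sG,
                 t_end, rec_t, rec_counts, snap_t, snap_states,
                 log_t, log_site, log_src, log_dst, seed):
    np.random.seed(seed)
    N = states.shape[0]
    rates = np.empty(N)
    tree = np.zeros(N + 1)
    _refresh(states, iF, jF, vF, iB, jB, vB, iG, jG, vG, wF, wB, wG,
             rates, tree, bG, bF, q, gam, phG, phA, mu,
             f0, f1, thF, sF, g0, g1, thG, sG)
    counts = np.zeros(4, np.int64)
    for i in range(N):
        counts[states[i]] += 1
    t = 0.0
    n_ev = 0
    n_log = 0
    rec_i = 0
    snap_i = 0
    log_cap = log_t.shape[0]
    while True:
        total = _fen_total(tree)
        if total <= 1e-300:
            break
        t_new = t + (-np.log(np.random.random()) / total)
        while rec_i < rec_t.shape[0] and rec_t[rec_i] <= t_new:
            for k in range(4):
                rec_counts[rec_i, k] = counts[k]
            rec_i += 1
        while snap_i < snap_t.shape[0] and snap_t[snap_i] <= t_new:
            for k in range(N):
                snap_states[snap_i, k] = states[k]
            snap_i += 1
        if t_new >= t_end:
            t = t_end
            break
        t = t_new
        u = np.random.random() * total
        i = _fen_find(tree, u)
        st = states[i]
        if rates[i] <= 0.0:
            continue
        # choose the destination state within site i
        if st == 0:
            r1 = bF * wB[i] + _sig_rate(wG[i], f0, f1, thF, sF)
            dst = 2 if np.random.random() * (r1 + mu) < r1 else 1
        elif st == 1:
            r1 = phG * wF[i]
            r2 = bG * wB[i] + _sig_rate(wG[i], g0, g1, thG, sG)
            dst = 0 if np.random.random() * (r1 + r2) < r1 else 2
        elif st == 2:
            dst = 3
        else:
            r1 = phA * wF[i]
            dst = 0 if np.random.random() * (r1 + gam) < r1 else 1
        states[i] = dst
        counts[st] -= 1
        counts[dst] += 1
        if n_log < log_cap:
            log_t[n_log] = t
            log_site[n_log] = i
            log_src[n_log] = st
            log_dst[n_log] = dst
            n_log += 1
        # update neighbour fields touched by the removed and added indicator
        if st == 0:
            for k in range(iF[i], iF[i + 1]):
                wF[jF[k]] -= vF[k]
        elif st == 1:
            for k in range(iG[i], iG[i + 1]):
                wG[jG[k]] -= vG[k]
        elif st == 2:
            for k in range(iB[i], iB[i + 1]):
                wB[jB[k]] -= vB[k]
        if dst == 0:
            for k in range(iF[i], iF[i + 1]):
                wF[jF[k]] += vF[k]
        elif dst == 1:
            for k in range(iG[i], iG[i + 1]):
                wG[jG[k]] += vG[k]
        elif dst == 2:
            for k in range(iB[i], iB[i + 1]):
                wB[jB[k]] += vB[k]
        # refresh the rates of every affected site (idempotent per site)
        if st == 0 or dst == 0:
            for k in range(iF[i], iF[i + 1]):
                _touch(jF[k], wF, wB, wG, states, rates, tree, bG, bF, q, gam,
                       phG, phA, mu, f0, f1, thF, sF, g0, g1, thG, sG)
        if st == 1 or dst == 1:
            for k in range(iG[i], iG[i + 1]):
                _touch(jG[k], wF, wB, wG, states, rates, tree, bG, bF, q, gam,
                       phG, phA, mu, f0, f1, thF, sF, g0, g1, thG, sG)
        if st == 2 or dst == 2:
            for k in range(iB[i], iB[i + 1]):
                _touch(jB[k], wF, wB, wG, states, rates, tree, bG, bF, q, gam,
                       phG, phA, mu, f0, f1, thF, sF, g0, g1, thG, sG)
        _touch(i, wF, wB, wG, states, rates, tree, bG, bF, q, gam,
               phG, phA, mu, f0, f1, thF, sF, g0, g1, thG, sG)
        n_ev += 1
        if n_ev % _REBUILD_EVERY == 0:
            _refresh(states, iF, jF, vF, iB, jB, vB, iG, jG, vG, wF, wB, wG,
                     rates, tree, bG, bF, q, gam, phG, phA, mu,
                     f0, f1, thF, sF, g0, g1, thG, sG)
    while rec_i < rec_t.shape[0]:
        for k in range(4):
            rec_counts[rec_i, k] = counts[k]
        rec_i += 1
    while snap_i < snap_t.shape[0]:
        for k in range(N):
            snap_states[snap_i, k] = states[k]
        snap_i += 1
    return n_ev, n_log, t


@njit(cache=True)
def _run_uniform(counts, N, bG, bF, q, gam, phG, phA, mu,
                 f0, f1, thF, sF, g0, g1, thG, sG,
                 t_end, rec_t, rec_counts, seed):
    np.random.seed(seed)
    t = 0.0
    n_ev = 0
    rec_i = 0
    r = np.empty(7)
    while True:
        nF, nG, nB, nA = counts[0], counts[1], counts[2], counts[3]
        wFf = nF / N
        wBf = nB / N
        r[0] = nG * phG * wFf                                    # G -> F
        r[1] = nG * (bG * wBf + _sig_rate((nG - 1) / N, g0, g1, thG, sG)) \
            if nG > 0 else 0.0                                   # G -> B
        r[2] = nF * (bF * wBf + _sig_rate(nG / N, f0, f1, thF, sF))  # F -> B
        r[3] = nF * mu                                           # F -> G
        r[4] = nB * q                                            # B -> A
        r[5] = nA * phA * wFf                                    # A -> F
        r[6] = nA * gam                                          # A -> G
        total = r.sum()
        if total <= 1e-300:
            break
        t_new = t + (-np.log(np.random.random()) / total)
        while rec_i < rec_t.shape[0] and rec_t[rec_i] <= t_new:
            for k in range(4):
                rec_counts[rec_i, k] = counts[k]
            rec_i += 1
        if t_new >= t_end:
            t = t_end
            break
        t = t_new
        u = np.random.random() * total
        c = 0
        acc = r[0]
        while acc <= u and c < 6:
            c += 1
            acc += r[c]
        if c == 0:
            counts[1] -= 1
            counts[0] += 1
        elif c == 1:
            counts[1] -= 1
            counts[2] += 1
        elif c == 2:
            counts[0] -= 1
            counts[2] += 1
        elif c == 3:
            counts[0] -= 1
            counts[1] += 1
        elif c == 4:
            counts[2] -= 1
            counts[3] += 1
        elif c == 5:
            counts[3] -= 1
            counts[0] += 1
        else:
            counts[3] -= 1
            counts[1] += 1
        n_ev += 1
    while rec_i < rec_t.shape[0]:
        for k in range(4):
            rec_counts[rec_i, k] = counts[k]
        rec_i += 1
    return n_ev, t


def _params_tuple(p: ParameterSet):
    return (p.beta_G, p.beta_F, p.q, p.gamma, p.phi_G, p.phi_A, p.mu,
            p.f0, p.f1, p.theta_F, p.s_F, p.g0, p.g1, p.theta_G, p.s_G)


def _record_times(t_end, record_dt):
    ks = np.arange(0, int(np.floor(t_end / record_dt + 1e-9)) + 1)
    rec = ks * record_dt
    if rec[-1] < t_end * (1 - 1e-12):
        rec = np.append(rec, t_end)
    else:
        rec[-1] = t_end
    return rec


def gillespie_run(config0: Configuration, params: ParameterSet, t_end, seed,
                  record_dt, snapshot_times=None, log_events=0,
                  uniform_kernels=False, in_place=False) -> Trajectory:
    """Run the exact SSA from ``config0`` to ``t_end`` (years).

    Cover fractions are recorded at every multiple of ``record_dt`` plus at
    ``t_end``; optional full-landscape ``snapshot_times`` and an event log of
    up to ``log_events`` events can be requested.  If the landscape becomes
    absorbing (zero total rate) the trajectory is padded with the final
    state.  Identical seeds reproduce identical runs bit for bit.  With
    ``uniform_kernels=True`` all kernels are flat (mean-field interactions)
    and an equivalent count-based SSA is used.
    """
    if t_end <= 0 or record_dt <= 0:
        raise ValueError("t_end and record_dt must be > 0")
    seed = int(seed) & 0x7FFFFFFF
    rec_t = _record_times(float(t_end), float(record_dt))
    rec_counts = np.zeros((rec_t.size, 4), dtype=np.int64)
    N = len(config0.sites)
    pt = _params_tuple(params)
    if uniform_kernels:
        counts = config0.counts().astype(np.int64)
        n_ev, _t = _run_uniform(counts, float(N), *pt, float(t_end), rec_t,
                                rec_counts, seed)
        return Trajectory(times=rec_t, fractions=rec_counts / N,
                          n_events=int(n_ev))
    config = config0 if in_place else config0.copy()
    config.ensure_fields(params)
    csrs = []
    for name in ("F", "B", "G"):
        m = config.kernels.csr[name]
        csrs.extend([m.indptr.astype(np.int64), m.indices.astype(np.int64),
                     m.data])
    snap_t = (np.sort(np.asarray(snapshot_times, dtype=float))
              if snapshot_times is not None else np.empty(0))
    snap_states = np.zeros((snap_t.size, N), dtype=np.int8)
    cap = int(log_events)
    log_t = np.zeros(cap)
    log_site = np.zeros(cap, dtype=np.int64)
    log_src = np.zeros(cap, dtype=np.int8)
    log_dst = np.zeros(cap, dtype=np.int8)
    n_ev, n_log, _t = _run_spatial(
        config.states, *csrs, config.wF, config.wB, config.wG, *pt,
        float(t_end), rec_t, rec_counts, snap_t, snap_states,
        log_t, log_site, log_src, log_dst, seed)
    events = None
    if cap:
        events = np.zeros(n_log, dtype=[("t", "f8"), ("site", "i8"),
                                        ("src", "i1"), ("dst", "i1")])
        events["t"] = log_t[:n_log]
        events["site"] = log_site[:n_log]
        events["src"] = log_src[:n_log]
        events["dst"] = log_dst[:n_log]
    snapshots = [(float(tv), snap_states[k].copy())
                 for k, tv in enumerate(snap_t)]
    return Trajectory(times=rec_t, fractions=rec_counts / N, events=events,
                      snapshots=snapshots, n_events=int(n_ev))
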