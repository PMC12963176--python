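"""Configuration loading, canonical fixtures, and delimited-text writers."""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .bifurcation import Branch
from .meanfield import MeanFieldState
from .params import ParameterSet, SiteSet, sample_sites
from .stochastic import STATE_LABELS, Configuration, make_initial_configuration
from .trajectory import Trajectory

__all__ = [
    "load_config",
    "save_config",
    "make_fixture",
    "FIXTURES",
    "write_trajectory",
    "read_trajectory",
    "write_snapshot",
    "read_snapshot",
    "write_branch",
    "RunManifest",
]

log = logging.getLogger("fgba")

_RUN_OPTION_KEYS = {"t_end", "record_dt", "seed", "x0", "param", "range",
                    "grid_n", "snapshot_times"}

_FMT = "%.12g"  # 12 significant digits everywhere


def load_config(path) -> tuple:
    """Read a flat key-value configuration file.

    Returns ``(ParameterSet, run_options)``.  Model-parameter keys must match
    :class:`ParameterSet` field names exactly; a reserved set of run-option
    keys (``t_end``, ``record_dt``, ``seed``, ...) is passed through in the
    second return value.  Unknown keys are an error; missing model parameters
    fall back to the package defaults with a logged notice.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must be a flat key-value mapping")
    known = set(ParameterSet.field_names())
    unknown = set(data) - known - _RUN_OPTION_KEYS
    if unknown:
        raise KeyError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    model = {k: v for k, v in data.items() if k in known}
    options = {k: v for k, v in data.items() if k in _RUN_OPTION_KEYS}
    params = ParameterSet.from_dict(model)
    missing = sorted(set(known) - set(model))
    if missing:
        log.info("config %s: using defaults for %s", path, ", ".join(missing))
    return params, options


def save_config(params: ParameterSet, path) -> None:
    params.save(path)


# --- canonical simulation setups -------------------------------------------
# Named, seeded reproductions of the reference experiments: the
# timescale-separated grassland runs ("fig9" single-ignition profile and the
# "fig10" q=15000 variant with regime switching), the 40% forest bistability
# landscape ("fig11"), and the mean-field low-forest onset protocol ("fig6").

_TS = dict(beta_G=5e4, beta_F=1e4, q=2e4, gamma=500.0, phi_G=1.0, phi_A=1.0,
           mu=0.01, f0=0.01, g0=0.01, f1=0.05, g1=0.1, N=2000, L=1.0,
           sigma_F=0.05, sigma_G=0.05, sigma_B=0.05)
_PARTIAL = dict(beta_G=50.0, beta_F=10.0, q=30.0, gamma=10.0, phi_G=1.0,
                phi_A=1.0, mu=0.01, f0=0.01, g0=0.01, f1=0.5, g1=1.0)

FIXTURES = ("fig9", "fig10", "fig11", "fig6")


def make_fixture(name: str, seed: int):
    """Return ``(ParameterSet, Configuration | MeanFieldState)`` for a named setup."""
    if name == "fig9":
        params = ParameterSet(**{**_TS, "sigma_B": 0.035})
        sites = sample_sites(params.N, params.L, seed)
        return params, make_initial_configuration(sites, {"G": 1.0}, seed)
    if name == "fig10":
        params = ParameterSet(**{**_TS, "q": 15000.0})
        sites = sample_sites(params.N, params.L, seed)
        return params, make_initial_configuration(sites, {"G": 1.0}, seed)
    if name == "fig11":
        params = ParameterSet(**{**_TS, "phi_G": 1.5, "phi_A": 1.5,
                                 "sigma_B": 0.03})
        sites = sample_sites(params.N, params.L, seed)
        return params, make_initial_configuration(
            sites, {"F": 0.4, "G": 0.6}, seed)
    if name == "fig6":
        params = ParameterSet(**_PARTIAL)
        return params, MeanFieldState(0.01, 0.99, 0.0, 0.0)
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")


# --- delimited text output ---------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Tab-delimited trajectory (t, F, G, B, A) at 12 significant digits."""
    data = np.column_stack([traj.times, traj.fractions])
    np.savetxt(path, data, fmt=_FMT, delimiter="\t",
               header="t\tF\tG\tB\tA", comments="")


def read_trajectory(path) -> Trajectory:
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    return Trajectory(times=data[:, 0], fractions=data[:, 1:5])


def write_snapshot(sites: SiteSet, states, path) -> None:
    """Per-site landscape snapshot as (x, y, state-label) rows."""
    states = np.asarray(states)
    with open(path, "w") as fh:
        fh.write("x\ty\tstate\n")
        for (x, y), s in zip(sites.positions, states):
            fh.write(f"{x:.12g}\t{y:.12g}\t{STATE_LABELS[int(s)]}\n")


def read_snapshot(path) -> tuple:
    xs, ys, codes = [], [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            x, y, s = line.split()
            xs.append(float(x))
            ys.append(float(y))
            codes.append(STATE_LABELS.index(s))
    return np.column_stack([xs, ys]), np.array(codes, dtype=np.int8)


def write_branch(branch: Branch, path) -> None:
    """Branch rows (param, F, G, B, A, max Re eig, label), sorted by parameter."""
    order = np.argsort(branch.values, kind="stable")
    labels = {}
    for lab, v, _state in branch.bifurcations:
        labels[min(range(len(branch)),
                   key=lambda i: abs(branch.values[i] - v))] = lab
    with open(path, "w") as fh:
        fh.write(f"{branch.pname}\tF\tG\tB\tA\tmax_real_eig\tlabel\n")
        for i in order:
            stab = {True: "stable", False: "unstable", None: "marginal"}[
                branch.stable[i]]
            lab = labels.get(i, stab)
            row = [branch.values[i], *branch.states[i], branch.max_real_eig[i]]
            fh.write("\t".join(_FMT % v for v in row) + f"\t{lab}\n")


@dataclass
class RunManifest:
    """What a command-line run did: parameters, seeds, outputs, provenance."""

    command: str
    params: ParameterSet
    seed: int | None
    outputs: list = field(default_factory=list)
    version: str = ""
    started: str = ""

    def __post_init__(self):
        if not self.started:
            self.started = datetime.datetime.now().isoformat(timespec="seconds")
        if not self.version:
            from . import __version__
            self.version = __version__

    def write(self, path) -> None:
        doc = {"command": self.command, "seed": self.seed,
               "version": self.version, "started": self.started,
               "outputs": list(self.outputs),
               "params": self.params.to_dict()}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
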