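"""Time-stamped land-cover trajectories shared by the stochastic and ODE solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Cover fractions (F, G, B, A) sampled at increasing record times.

    ``fractions`` has shape (n_times, 4) with columns ordered F, G, B, A;
    every row sums to one.  Stochastic runs may attach an event log
    (structured array with fields t, site, src, dst) and full landscape
    snapshots ``[(t, states), ...]``.
    """

    times: np.ndarray
    fractions: np.ndarray
    events: np.ndarray | None = None
    snapshots: list = field(default_factory=list)
    n_events: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.times.size, 4):
            raise ValueError("fractions must have shape (len(times), 4)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("record times must be strictly increasing")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValueError("cover fractions must lie in [0, 1]")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("cover fractions must sum to 1 at every record")

    @property
    def F(self) -> np.ndarray:
        return self.fractions[:, 0]

    @property
    def G(self) -> np.ndarray:
        return self.fractions[:, 1]

    @property
    def B(self) -> np.ndarray:
        return self.fractions[:, 2]

    @property
    def A(self) -> np.ndarray:
        return self.fractions[:, 3]

    def final(self) -> np.ndarray:
        return self.fractions[-1]

    def __len__(self) -> int:
        return self.times.size
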