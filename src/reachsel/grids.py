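"""Periodic functions of target direction on a uniform grid over [0, 360)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DirectionalFunction:
    """A real-valued function of direction, stored on a uniform circular grid.

    The grid covers [0, 360) at ``resolution`` degrees per node (resolution
    must divide 360). Evaluation at arbitrary directions uses periodic linear
    interpolation between the two bracketing nodes; learning updates are
    applied directly to node values.
    """

    resolution: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = 360.0 / self.resolution
        if self.resolution <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(f"resolution must evenly divide 360, got {self.resolution}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (int(round(n)),):
            raise ValueError(
                f"values must have shape ({int(round(n))},) for resolution {self.resolution}"
            )

    @classmethod
    def zeros(cls, resolution: float = 1.0) -> "DirectionalFunction":
        n = 360.0 / resolution
        if resolution <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(f"resolution must evenly divide 360, got {resolution}")
        return cls(resolution, np.zeros(int(round(n))))

    @classmethod
    def constant(cls, value: float, resolution: float = 1.0) -> "DirectionalFunction":
        fn = cls.zeros(resolution)
        fn.values[:] = value
        return fn

    @property
    def n_nodes(self) -> int:
        return self.values.size

    @property
    def grid(self) -> np.ndarray:
        """Node directions in degrees, ``[0, resolution, ..., 360 - resolution]``."""
        return np.arange(self.n_nodes) * self.resolution

    def value_at(self, theta):
        """Evaluate at direction(s) ``theta`` (degrees, any real) by periodic
        linear interpolation."""
        pos = (np.asarray(theta, dtype=float) % 360.0) / self.resolution
        i0 = np.floor(pos).astype(int) % self.n_nodes
        frac = pos - np.floor(pos)
        i1 = (i0 + 1) % self.n_nodes
        out = self.values[i0] * (1.0 - frac) + self.values[i1] * frac
        return float(out) if np.ndim(theta) == 0 else out

    def copy(self) -> "DirectionalFunction":
        return DirectionalFunction(self.resolution, self.values.copy())
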