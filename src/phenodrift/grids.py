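"""Uniform grids over 1-D phenotype (formaldehyde-tolerance) space.

Tolerance is measured in mM formaldehyde: the maximum medium concentration
at which a cell can still grow.  The grid always starts at 0 mM (tolerance
cannot be negative) and extends to an upper boundary L chosen above the
highest tolerance present in the data so that upward phenotype transitions
are not artificially constrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ToleranceGrid"]


@dataclass(frozen=True)
class ToleranceGrid:
    """Uniform discretization of tolerance space [0, L].

    Parameters
    ----------
    L : float
        Upper boundary of tolerance space (mM).  Must exceed the highest
        observed tolerance of the data the grid serves.
    dx : float, optional
        Grid spacing (mM).  Default 0.01 mM.
    """

    L: float
    dx: float = 0.01
    x: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"upper boundary L must be positive, got {self.L}")
        if self.dx <= 0:
            raise ValueError(f"grid step dx must be positive, got {self.dx}")
        n = round(self.L / self.dx) + 1
        if not np.isclose((n - 1) * self.dx, self.L, rtol=1e-9, atol=1e-12):
            raise ValueError(f"L={self.L} is not an integer multiple of dx={self.dx}")
        object.__setattr__(self, "x", np.linspace(0.0, self.L, n))

    @property
    def n_bins(self) -> int:
        return self.x.size

    def index_of(self, level: float) -> int:
        """Index of the grid point at ``level`` mM; raises if misaligned."""
        i = int(round(level / self.dx))
        if i < 0 or i >= self.n_bins or not np.isclose(self.x[i], level, atol=1e-9):
            raise ValueError(f"level {level} mM does not lie on the grid (dx={self.dx}, L={self.L})")
        return i

    def covers(self, levels: np.ndarray) -> bool:
        levels = np.asarray(levels, dtype=float)
        return bool(levels.min() >= 0.0 and levels.max() <= self.L + 1e-12)
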