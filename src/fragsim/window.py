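"""Observation window for point patterns and landscapes.

The simulation arena is a rectangle, by default the unit square, with either
planar or toroidal (periodic) topology. Toroidal topology is the package
default: offspring displacement and inter-point distances wrap around the
edges, which keeps the intensity of generated processes spatially uniform
and avoids edge effects in the diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Window"]


@dataclass(frozen=True)
class Window:
    """Rectangular observation window.

    Parameters
    ----------
    x_min, y_min, x_max, y_max : float
        Window bounds, dimensionless. Defaults give the unit square.
    topology : {"toroidal", "planar"}
        Metric used for distances and for wrapping points generated
        outside the bounds. Default "toroidal".
    """

    x_min: float = 0.0
    y_min: float = 0.0
    x_max: float = 1.0
    y_max: float = 1.0
    topology: str = "toroidal"

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive extent on both axes")
        if self.topology not in ("toroidal", "planar"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-window test (closed bounds)."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    def wrap(self, x, y):
        """Map coordinates into the window by periodic wrapping."""
        x = self.x_min + np.mod(np.asarray(x, dtype=float) - self.x_min, self.width)
        y = self.y_min + np.mod(np.asarray(y, dtype=float) - self.y_min, self.height)
        return x, y

    def separations(self, xy_a: np.ndarray, xy_b: np.ndarray) -> np.ndarray:
        """Pairwise distance matrix between two (n,2) coordinate arrays.

        Respects the window topology: toroidal windows use the shortest
        wrapped displacement on each axis.
        """
        dx = np.abs(xy_a[:, None, 0] - xy_b[None, :, 0])
        dy = np.abs(xy_a[:, None, 1] - xy_b[None, :, 1])
        if self.topology == "toroidal":
            dx = np.minimum(dx, self.width - dx)
            dy = np.minimum(dy, self.height - dy)
        return np.hypot(dx, dy)
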