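"""Fragmented habitat landscapes.

Binary habitat maps are built by thresholding fractal surfaces generated with
the midpoint displacement (diamond-square) algorithm. The Hurst factor H in
(0, 1) controls the ruggedness of the surface and thereby fragmentation per
se: smooth surfaces (H near 1) yield few large contiguous fragments, rugged
surfaces (H near 0) yield many small scattered fragments, at identical
habitat amount. The fractal dimension of the surface is D = 3 - H.

Thresholding is done by rank so that the habitat-cell count is exact:
the k = round-half-up(p * n_cells) highest-valued cells become habitat.

For comparison with the analytic survival solution, landscapes of equally
sized circular fragments (a Boolean disk model with fixed disk count) are
also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from fragsim.window import Window

__all__ = [
    "FractalSurface",
    "HabitatMap",
    "DiskLandscape",
    "midpoint_displacement",
    "threshold_to_habitat",
    "make_disk_landscape",
    "is_habitat",
    "patch_count",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_disk_landscape",
    "read_disk_landscape",
]


@dataclass(frozen=True)
class FractalSurface:
    """Real-valued square grid from midpoint displacement."""

    values: np.ndarray
    hurst: float
    levels: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        side = 2 ** self.levels + 1
        v = np.asarray(self.values, dtype=float)
        if v.shape != (side, side):
            raise ValueError(f"expected a {side}x{side} grid for levels={self.levels}")
        if not np.all(np.isfinite(v)):
            raise ValueError("surface contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def fractal_dimension(self) -> float:
        return 3.0 - self.hurst


@dataclass(frozen=True)
class HabitatMap:
    """Binary raster over the window: True = habitat, False = matrix."""

    grid: np.ndarray
    habitat_amount: float
    window: Window = field(default_factory=Window)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("grid must be a square 2-D array")
        object.__setattr__(self, "grid", g)

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    @property
    def n_habitat_cells(self) -> int:
        return int(self.grid.sum())

    @property
    def realized_amount(self) -> float:
        return self.n_habitat_cells / self.grid.size


@dataclass(frozen=True)
class DiskLandscape:
    """Equal-radius circular habitat fragments with random centres.

    Overlaps are permitted (Boolean model), so the realized covered
    fraction can be below the nominal habitat amount ``habitat_amount``
    = n_disks * pi * R^2 / A.
    """

    centres: np.ndarray
    radius: float
    window: Window = field(default_factory=Window)
    habitat_amount: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centres, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centres", c)
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if c.size and not np.all(self.window.contains(c[:, 0], c[:, 1])):
            raise ValueError("all centres must lie inside the window")

    @property
    def n_disks(self) -> int:
        return self.centres.shape[0]

    def realized_coverage(self, resolution: int = 512) -> float:
        """Covered area fraction, measured on a raster of given resolution."""
        g = rasterize_disks(self, resolution, antialias=True)
        return float(g.mean())


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def midpoint_displacement(hurst: float, levels: int = 7,
                          seed=None) -> FractalSurface:
    """Generate a fractal surface by diamond-square midpoint displacement.

    Classic recursion without random additions: the four corners start from
    standard normals; at recursion level l (l = 1..levels) every new midpoint
    is the average of its neighbours plus a normal perturbation with standard
    deviation (1/2)**(l*H). The result is a (2**levels + 1) square grid.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in the open interval (0, 1)")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    side = 2 ** levels + 1
    z = np.zeros((side, side))
    z[0, 0], z[0, -1], z[-1, 0], z[-1, -1] = rng.normal(size=4)
    step = side - 1
    for level in range(1, levels + 1):
        sd = 0.5 ** (level * hurst)
        half = step // 2
        # diamond step: centres of squares get the mean of 4 corners
        cr = np.arange(half, side, step)
        cc = np.arange(half, side, step)
        corners = (z[np.ix_(cr - half, cc - half)] + z[np.ix_(cr - half, cc + half)]
                   + z[np.ix_(cr + half, cc - half)] + z[np.ix_(cr + half, cc + half)])
        z[np.ix_(cr, cc)] = corners / 4.0 + rng.normal(0.0, sd, (cr.size, cc.size))
        # square step: edge midpoints get the mean of their (3 or 4) neighbours
        sd_sq = sd * 0.5 ** (0.5 * hurst)
        mask = np.zeros((side, side), dtype=bool)
        for row in range(0, side, half):
            offset = half if (row // half) % 2 == 0 else 0
            mask[row, offset::step] = True
        mask &= z == 0  # only unset midpoints (set cells are never exactly 0 a.s.)
        rows, cols = np.nonzero(mask)
        acc = np.zeros(rows.size)
        cnt = np.zeros(rows.size)
        for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
            rr, cc2 = rows + dr, cols + dc
            ok = (rr >= 0) & (rr < side) & (cc2 >= 0) & (cc2 < side)
            acc[ok] += z[rr[ok], cc2[ok]]
            cnt[ok] += 1
        z[rows, cols] = acc / cnt + rng.normal(0.0, sd_sq, rows.size)
        step = half
    return FractalSurface(z, hurst, levels,
                          seed if isinstance(seed, int) else None)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def threshold_to_habitat(surface: FractalSurface, habitat_amount: float,
                         tie_seed=0) -> HabitatMap:
    """Slice a fractal surface so that exactly k cells are habitat.

    k = round-half-up(habitat_amount * n_cells); the k highest-valued cells
    become habitat. Ties at the cut value (measure-zero for continuous
    surfaces) are broken uniformly at random using tie_seed.
    """
    if not 0.0 <= habitat_amount <= 1.0:
        raise ValueError("habitat_amount must be in [0, 1]")
    v = surface.values.ravel()
    n = v.size
    k = _round_half_up(habitat_amount * n)
    grid = np.zeros(n, dtype=bool)
    if k >= n:
        grid[:] = True
    elif k > 0:
        part = np.argpartition(v, n - k)
        top = part[n - k:]
        cut = v[top].min()
        if (v == cut).sum() > 1:
            # random tie-break at the cut value
            rng = np.random.default_rng(tie_seed)
            above = np.nonzero(v > cut)[0]
            tied = np.nonzero(v == cut)[0]
            need = k - above.size
            grid[above] = True
            grid[rng.choice(tied, size=need, replace=False)] = True
        else:
            grid[top] = True
    return HabitatMap(grid.reshape(surface.values.shape), habitat_amount)


def make_disk_landscape(n_disks: int, habitat_amount: float,
                        window: Window = Window(), seed=None) -> DiskLandscape:
    """Place n_disks equal-radius disks with uniform random centres.

    The common radius R satisfies n_disks * pi * R**2 = habitat_amount * A,
    i.e. the *nominal* coverage equals the habitat amount; overlaps are
    permitted, so realized coverage can be lower.
    """
    if n_disks < 1:
        raise ValueError("n_disks must be >= 1")
    if not 0.0 < habitat_amount < 1.0:
        raise ValueError("habitat_amount must be in (0, 1)")
    radius = math.sqrt(habitat_amount * window.area / (n_disks * math.pi))
    if 2 * radius > min(window.width, window.height):
        raise ValueError("disk diameter exceeds the window side")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cx = rng.uniform(window.x_min, window.x_max, size=n_disks)
    cy = rng.uniform(window.y_min, window.y_max, size=n_disks)
    return DiskLandscape(np.column_stack([cx, cy]), radius, window, habitat_amount)


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def _cell_indices(landscape: HabitatMap, x, y):
    w = landscape.window
    side = landscape.side
    col = np.minimum((np.asarray(x) - w.x_min) / w.width * side, side - 1).astype(int)
    row = np.minimum((np.asarray(y) - w.y_min) / w.height * side, side - 1).astype(int)
    return row, col


def is_habitat(landscape: Union[HabitatMap, DiskLandscape], x, y):
    """Whether point(s) (x, y) fall in habitat.

    Raster maps use half-open cells [i*c, (i+1)*c), with the x=1 / y=1
    boundary assigned to the last cell. Disk landscapes test the toroidal
    distance to the nearest centre against the radius (boundary inclusive).
    Points outside the window raise ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    if not np.all(landscape.window.contains(x, y)):
        raise ValueError("point outside the landscape window")
    if isinstance(landscape, HabitatMap):
        row, col = _cell_indices(landscape, x, y)
        out = landscape.grid[row, col]
    else:
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        if landscape.n_disks == 0:
            out = np.zeros(pts.shape[0], dtype=bool)
        else:
            d = landscape.window.separations(pts, landscape.centres)
            out = (d.min(axis=1) <= landscape.radius)
        if scalar:
            out = out.reshape(())
    return bool(out) if scalar else out


def rasterize_disks(landscape: DiskLandscape, resolution: int,
                    antialias: bool = False) -> np.ndarray:
    """Raster of the disk union on a resolution x resolution grid.

    With ``antialias=True`` boundary cells get fractional coverage estimated
    from the signed distance to the disk edge (linear ramp over one cell).
    """
    w = landscape.window
    res = resolution
    xs = w.x_min + (np.arange(res) + 0.5) / res * w.width
    ys = w.y_min + (np.arange(res) + 0.5) / res * w.height
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = landscape.window.separations(pts, landscape.centres).min(axis=1)
    if antialias:
        cell = w.width / res
        g = np.clip((landscape.radius - d) / cell + 0.5, 0.0, 1.0)
    else:
        g = (d <= landscape.radius).astype(float)
    return g.reshape(res, res)


def patch_count(landscape: HabitatMap, connectivity: int = 1) -> int:
    """Number of connected habitat patches (4-connected by default)."""
    structure = ndimage.generate_binary_structure(2, connectivity)
    _, n = ndimage.label(landscape.grid, structure=structure)
    return int(n)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(landscape: HabitatMap, path: Union[str, Path],
                     nodata: int = -9999) -> None:
    """Write a habitat map as an ESRI ASCII grid (habitat=1, matrix=0)."""
    path = Path(path)
    w = landscape.window
    side = landscape.side
    header = (
        f"ncols {side}\n"
        f"nrows {side}\n"
        f"xllcorner {w.x_min}\n"
        f"yllcorner {w.y_min}\n"
        f"cellsize {w.width / side}\n"
        f"NODATA_value {nodata}\n"
    )
    # ESRI grids store the top row first
    body = np.flipud(landscape.grid.astype(int))
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%d")


def read_ascii_grid(path: Union[str, Path]) -> HabitatMap:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    body = np.loadtxt(lines[n_header:])
    grid = np.flipud(np.atleast_2d(body)).astype(bool)
    side = grid.shape[0]
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0)
    cs = header.get("cellsize", 1.0 / side)
    window = Window(x0, y0, x0 + cs * side, y0 + cs * side)
    return HabitatMap(grid, grid.mean(), window)


def write_disk_landscape(landscape: DiskLandscape, path: Union[str, Path]) -> None:
    """Write disk centres and radius as CSV with header cx,cy,r."""
    arr = np.column_stack([landscape.centres,
                           np.full(landscape.n_disks, landscape.radius)])
    np.savetxt(path, arr, delimiter=",", header="cx,cy,r", comments="")


def read_disk_landscape(path: Union[str, Path],
                        window: Window = Window()) -> DiskLandscape:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    radius = float(arr[0, 2])
    nominal = arr.shape[0] * math.pi * radius ** 2 / window.area
    return DiskLandscape(arr[:, :2], radius, window, nominal)
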